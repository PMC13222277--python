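"""Survey/catalog readers and writers, packaged fixtures, pipeline driver.

Survey files are long-format CSV with the exact header
``expert_id,involvement,criterion,dimension,rating`` (UTF-8, comma
separated, LF line endings); catalogs are CSV with header
``code,label,axis,aspect,granularity``.  Validation is collected into a
single structured error listing every offending row, so a malformed
file is diagnosed in one pass.

The packaged fixtures carry the reference study's criteria catalog, its
reported per-criterion defuzzified scores and closeness coefficients,
and the involvement linguistic scale; they let the screening and fusion
stages be reproduced even though the underlying survey is not public.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .delphi import screen_panel
from .fusion import annotate_framework, unify
from .fuzzy import DEFAULT_SCALES, LinguisticScale
from .panel import (
    ASPECTS,
    AXES,
    DIMENSIONS,
    CriterionDescriptor,
    PanelValidationError,
    SurveyPanel,
)
from .topsis import CONVENTIONS, rank_criteria

__all__ = [
    "SURVEY_COLUMNS",
    "read_survey",
    "write_survey",
    "read_catalog",
    "load_fixture",
    "FIXTURES",
    "RunConfig",
    "run_pipeline",
    "reproduce_reference",
]

log = logging.getLogger("panelrank")

SURVEY_COLUMNS = ["expert_id", "involvement", "criterion", "dimension", "rating"]
CATALOG_COLUMNS = ["code", "label", "axis", "aspect", "granularity"]

FIXTURES = (
    "criteria_catalog",
    "reference_g_values",
    "involvement_scale",
    "reference_cc_values",
)


def _data_text(name: str) -> str:
    return resources.files("panelrank").joinpath("data", name).read_text(encoding="utf-8")


def read_survey(path: str | Path) -> SurveyPanel:
    """Read and validate a long-format survey CSV into a :class:`SurveyPanel`.

    Problems (bad header, non-integer or out-of-range ratings, unknown
    dimensions, inconsistent involvement, duplicate cells) are reported
    together in a :class:`PanelValidationError` citing row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelValidationError([f"{path}: file is empty"]) from None
        if [h.strip() for h in header] != SURVEY_COLUMNS:
            raise PanelValidationError(
                [f"{path}: header {header!r} does not match {SURVEY_COLUMNS!r}"]
            )
        problems: list[str] = []
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                problems.append(f"row {lineno}: expected 5 fields, got {len(row)}")
                continue
            expert, inv, criterion, dimension, rating = (c.strip() for c in row)
            if dimension not in DIMENSIONS:
                problems.append(f"row {lineno}: unknown dimension {dimension!r}")
                continue
            try:
                inv_i = _parse_likert(inv)
            except ValueError as e:
                problems.append(f"row {lineno}: involvement {e}")
                continue
            try:
                rating_i = _parse_likert(rating)
            except ValueError as e:
                problems.append(f"row {lineno}: rating {e}")
                continue
            rows.append((expert, inv_i, criterion, dimension, rating_i))
    if not rows and not problems:
        problems.append(f"{path}: no rating rows")
    if problems:
        raise PanelValidationError(problems)
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    inconsistent = df.groupby("expert_id")["involvement"].nunique()
    problems = [
        f"expert {e!r}: inconsistent involvement levels across rows"
        for e in inconsistent[inconsistent > 1].index
    ]
    if problems:
        raise PanelValidationError(problems)
    experts = df[["expert_id", "involvement"]].drop_duplicates().reset_index(drop=True)
    ratings = df[["expert_id", "criterion", "dimension", "rating"]]
    return SurveyPanel(experts, ratings)


def _parse_likert(text: str) -> int:
    try:
        v = float(text)
    except ValueError:
        raise ValueError(f"{text!r} is not a number") from None
    if not v.is_integer() or not 1 <= v <= 5:
        raise ValueError(f"{text!r} is not an integer in 1..5")
    return int(v)


def write_survey(panel: SurveyPanel, path: str | Path) -> None:
    """Write a panel as survey CSV (LF endings); inverse of :func:`read_survey`."""
    inv = panel.involvement_levels()
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SURVEY_COLUMNS)
        for _, row in panel.ratings.iterrows():
            writer.writerow(
                [
                    row["expert_id"],
                    int(inv[row["expert_id"]]),
                    row["criterion"],
                    row["dimension"],
                    int(row["rating"]),
                ]
            )


def read_catalog(path_or_text: str | Path) -> list[CriterionDescriptor]:
    """Read a criteria catalog CSV into validated descriptors."""
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames != CATALOG_COLUMNS:
        raise ValueError(
            f"catalog header {reader.fieldnames!r} does not match {CATALOG_COLUMNS!r}"
        )
    out = []
    seen = set()
    for row in reader:
        if row["code"] in seen:
            raise ValueError(f"duplicate catalog code {row['code']!r}")
        seen.add(row["code"])
        out.append(CriterionDescriptor(**row))
    if not out:
        raise ValueError("catalog is empty")
    return out


def load_fixture(name: str):
    """Load a packaged fixture by name.

    * ``criteria_catalog`` -> list of :class:`CriterionDescriptor` (27 entries);
    * ``reference_g_values`` -> DataFrame of the reference study's
      defuzzified scores, indexed by criterion with columns
      ``relevance`` and ``applicability``;
    * ``involvement_scale`` -> the involvement :class:`LinguisticScale`;
    * ``reference_cc_values`` -> DataFrame of the reference study's
      closeness coefficients and printed ranks, indexed by criterion.
    """
    if name == "criteria_catalog":
        return read_catalog(_data_text("criteria_catalog.csv"))
    if name == "reference_g_values":
        df = pd.read_csv(
            resources.files("panelrank").joinpath("data", "reference_g_values.csv")
        ).set_index("criterion")
        if list(df.columns) != list(DIMENSIONS) or len(df) != 27:
            raise ValueError("reference_g_values fixture is malformed")
        return df
    if name == "involvement_scale":
        return LinguisticScale.from_yaml(_data_text("involvement_scale.yaml"))
    if name == "reference_cc_values":
        df = pd.read_csv(
            resources.files("panelrank").joinpath("data", "reference_cc_values.csv")
        ).set_index("criterion")
        if len(df) != 21:
            raise ValueError("reference_cc_values fixture is malformed")
        return df
    raise ValueError(f"unknown fixture {name!r}; choose one of {FIXTURES}")


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    survey: str | Path
    out_dir: str | Path
    catalog: str | Path | None = None  # packaged catalog when None
    convention: str = "per_column"
    rounding: str = "half_up"
    report_digits: int = 2
    seed: int | None = None
    formats: Sequence[str] = ("csv", "json")
    plot: bool = True
    scales: Mapping[str, LinguisticScale] = field(default_factory=lambda: dict(DEFAULT_SCALES))

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; choose one of {CONVENTIONS}"
            )
        if self.rounding != "half_up":
            raise ValueError(f"unknown rounding mode {self.rounding!r}; only 'half_up'")
        bad = set(self.formats) - {"csv", "json"}
        if bad:
            raise ValueError(f"unknown report formats {sorted(bad)}")
        for dim in DIMENSIONS:
            if dim not in self.scales or "involvement" not in self.scales:
                raise ValueError("scales must define relevance, applicability, involvement")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run validate -> screening -> TOPSIS (both dimensions) -> fusion -> reports.

    Reports are staged in a temporary directory and moved into place
    only when every stage has succeeded, so a failing stage leaves no
    partial outputs behind.  Returns a summary dict with the screening
    outcome, rankings and manifest.
    """
    survey_path = Path(config.survey)
    log.info("stage=validate reading survey %s", survey_path)
    panel = read_survey(survey_path)
    catalog = (
        load_fixture("criteria_catalog")
        if config.catalog is None
        else read_catalog(Path(config.catalog))
    )
    codes = [d.code for d in catalog]
    try:
        panel.require_complete(codes)
    except PanelValidationError as e:
        raise PanelValidationError([f"stage=validate: {p}" for p in e.problems]) from None

    log.info("stage=fdm aggregating %d criteria x %d experts", len(codes), panel.n_experts)
    fdm_results, outcome = screen_panel(panel, codes, config.scales)
    log.info(
        "stage=screen alpha_rel=%.4f alpha_app=%.4f excluded=%s",
        outcome.alpha_relevance,
        outcome.alpha_applicability,
        outcome.excluded,
    )
    retained = outcome.retained
    log.info("stage=topsis ranking %d retained criteria (%s)", len(retained), config.convention)
    topsis = {
        dim: rank_criteria(
            panel,
            retained,
            dim,
            config.scales[dim],
            involvement_scale=config.scales["involvement"],
            convention=config.convention,
        )
        for dim in DIMENSIONS
    }
    log.info("stage=fusion unifying rankings")
    unified = unify(topsis["relevance"], topsis["applicability"])
    annotation = annotate_framework(catalog, outcome, unified)

    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".panelrank-", dir=out_dir.parent))
    try:
        _write_reports(
            staging, config, survey_path, panel, fdm_results, outcome, topsis, unified,
            annotation,
        )
        out_dir.mkdir(exist_ok=True)
        for item in staging.iterdir():
            shutil.move(str(item), out_dir / item.name)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    log.info("stage=report wrote reports to %s", out_dir)
    return {
        "screening": outcome,
        "topsis": topsis,
        "unified": unified,
        "annotation": annotation,
        "out_dir": out_dir,
    }


def _write_reports(
    staging: Path, config: RunConfig, survey_path: Path, panel, fdm_results, outcome,
    topsis, unified, annotation,
) -> None:
    fdm_rows = [
        {
            "criterion": r.criterion,
            "dimension": r.dimension,
            "L": r.aggregate.l,
            "M": r.aggregate.m,
            "U": r.aggregate.u,
            "G": r.g,
        }
        for dim in DIMENSIONS
        for r in fdm_results[dim]
    ]
    screening_df = outcome.to_frame()
    topsis_frames = {}
    for dim in DIMENSIONS:
        df = topsis[dim].table.copy()
        df.insert(0, "criterion", df.index)
        df.insert(1, "dimension", dim)
        topsis_frames[dim] = df.reset_index(drop=True)
    unified_report = unified.report(config.report_digits)

    if "csv" in config.formats:
        pd.DataFrame(fdm_rows).to_csv(staging / "fdm_results.csv", index=False)
        screening_df.to_csv(staging / "screening.csv", index=False)
        for dim in DIMENSIONS:
            topsis_frames[dim].to_csv(staging / f"topsis_{dim}.csv", index=False)
        unified_report.to_csv(staging / "unified_ranking.csv", index=False)
    if "json" in config.formats:
        report = {
            "alpha": {
                "relevance": outcome.alpha_relevance,
                "applicability": outcome.alpha_applicability,
            },
            "screening": screening_df.to_dict(orient="records"),
            "unified_ranking": unified_report.to_dict(orient="records"),
            "framework_annotation": annotation,
        }
        (staging / "report.json").write_text(
            json.dumps(report, indent=2), encoding="utf-8"
        )
    if config.plot:
        from .plots import quadrant_scatter

        quadrant_scatter(outcome, staging / "quadrants.png")
        quadrant_scatter(outcome, staging / "quadrants.svg")

    manifest = {
        "package": "panelrank",
        "version": __version__,
        "survey": {"path": str(survey_path), "sha256": _sha256(survey_path)},
        "catalog": "packaged" if config.catalog is None else str(config.catalog),
        "n_experts": panel.n_experts,
        "n_criteria": len(screening_df),
        "convention": config.convention,
        "rounding": config.rounding,
        "seed": config.seed,
        "scales": {k: v.name for k, v in config.scales.items()},
    }
    (staging / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def reproduce_reference(out_dir: str | Path | None = None) -> dict:
    """Re-run the downstream stages from the packaged reference fixtures.

    The reference study's survey is not public, so its per-criterion
    defuzzified scores and closeness coefficients are packaged and the
    stages downstream of them — cut-offs, quadrant screening and the
    unified priority ranking — are recomputed from scratch.  Optionally
    writes the screening and ranking reports to ``out_dir``.
    """
    from .delphi import compute_cutoff, screen_criteria

    g = load_fixture("reference_g_values")
    alpha = {dim: compute_cutoff(g[dim]) for dim in DIMENSIONS}
    outcome = screen_criteria(
        g["relevance"].to_dict(),
        g["applicability"].to_dict(),
        alpha["relevance"],
        alpha["applicability"],
    )
    cc = load_fixture("reference_cc_values")
    unified = unify(cc["cc_relevance"].to_dict(), cc["cc_applicability"].to_dict())
    result = {"alpha": alpha, "screening": outcome, "unified": unified}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outcome.to_frame().to_csv(out / "screening.csv", index=False)
        unified.report().to_csv(out / "unified_ranking.csv", index=False)
        from .plots import quadrant_scatter

        quadrant_scatter(outcome, out / "quadrants.png")
    return result
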