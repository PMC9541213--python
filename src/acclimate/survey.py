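"""Summaries of a literature survey of acclimation-rate studies.

Each :class:`SurveyRecord` is one published study: its organism kind, the
environmental variable(s) manipulated, the trait measurements it reports
(each with the number of post-shift measurement occasions), its control-group
design, and whether it formally quantified the rate of plasticity.  The
summarizer produces the study-level and measurement-level proportions plus
the grand mean of per-study mean measurement counts — the statistics a
methodological review of this literature reports.

Vocabularies (the 13 environmental-variable categories, trait categories)
ship as editable defaults and can be overridden from a JSON config, since
different surveys slice these differently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)

#: Default category vocabularies (user-overridable; see :func:`load_vocabulary`).
DEFAULT_ENVIRONMENTAL_VARIABLES: tuple[str, ...] = (
    "temperature", "salinity", "light", "photoperiod", "oxygen", "pH",
    "carbon_dioxide", "humidity", "desiccation", "nutrients", "antibiotics",
    "pressure", "other_chemical",
)
DEFAULT_TRAIT_CATEGORIES: tuple[str, ...] = (
    "biochemical", "physiological", "morphological", "behavioural",
    "performance", "life_history", "other",
)
ORGANISM_KINDS: tuple[str, ...] = ("bacteria", "plant", "animal")
CONTROL_DESIGNS: tuple[str, ...] = ("none", "initial_only", "initial_and_new")


@dataclass(frozen=True)
class TraitMeasurement:
    trait_category: str
    n_timepoints: int

    def __post_init__(self):
        if self.n_timepoints < 1:
            raise DataValidationError(
                f"n_timepoints must be >= 1, got {self.n_timepoints}")


@dataclass(frozen=True)
class SurveyRecord:
    """One study in the survey."""

    study_id: str
    year: int
    organism_kind: str
    environmental_variables: tuple[str, ...]
    traits: tuple[TraitMeasurement, ...]
    control_design: str
    formal_quantification: bool

    def __post_init__(self):
        if self.year < 1900:
            raise DataValidationError(f"year must be >= 1900, got {self.year}")
        if not self.traits:
            raise DataValidationError(
                f"study {self.study_id!r} has no trait measurements")
        if not self.environmental_variables:
            raise DataValidationError(
                f"study {self.study_id!r} has no environmental variable")

    @property
    def mean_timepoints(self) -> float:
        return sum(t.n_timepoints for t in self.traits) / len(self.traits)


@dataclass
class SurveySummary:
    n_studies: int
    n_trait_measurements: int
    trait_category_proportions: dict[str, float]
    environmental_variable_proportions: dict[str, float]
    n_multi_variable_excluded: int
    organism_kind_proportions: dict[str, float]
    control_design_proportions: dict[str, float]
    studies_per_year: dict[int, int]
    per_study_mean_timepoints: dict[str, float]
    grand_mean_timepoints: float
    n_formal_quantification: int
    pct_formal_quantification: float  # percentage, 1 d.p.

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        payload = {
            k: (dict(sorted(v.items())) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        text = json.dumps(payload, indent=indent, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (section, category, value)."""
        rows = []
        sections = {
            "trait_category": self.trait_category_proportions,
            "environmental_variable": self.environmental_variable_proportions,
            "organism_kind": self.organism_kind_proportions,
            "control_design": self.control_design_proportions,
        }
        for section, mapping in sections.items():
            for cat, val in sorted(mapping.items()):
                rows.append({"section": section, "category": str(cat),
                             "statistic": "proportion", "value": val})
        for year, n in sorted(self.studies_per_year.items()):
            rows.append({"section": "year", "category": str(year),
                         "statistic": "n_studies", "value": n})
        rows.append({"section": "timepoints", "category": "grand_mean",
                     "statistic": "mean_of_per_study_means",
                     "value": self.grand_mean_timepoints})
        rows.append({"section": "formal_quantification", "category": "pct",
                     "statistic": "percentage",
                     "value": self.pct_formal_quantification})
        return pd.DataFrame(rows)


def load_vocabulary(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Load the category vocabulary, defaulting to the shipped one.

    The JSON file may override any of ``environmental_variables``,
    ``trait_categories``, ``organism_kinds``, ``control_designs``.
    """
    vocab = {
        "environmental_variables": DEFAULT_ENVIRONMENTAL_VARIABLES,
        "trait_categories": DEFAULT_TRAIT_CATEGORIES,
        "organism_kinds": ORGANISM_KINDS,
        "control_designs": CONTROL_DESIGNS,
    }
    if path is not None:
        user = json.loads(Path(path).read_text())
        for key, val in user.items():
            if key not in vocab:
                raise DataValidationError(f"unknown vocabulary section {key!r}")
            vocab[key] = tuple(val)
    return vocab


def validate_records(records: Sequence[SurveyRecord],
                     vocab: Mapping[str, tuple[str, ...]] | None = None) -> None:
    """Check every categorical field against the vocabulary; list all offenders."""
    vocab = vocab or load_vocabulary()
    offenders: list[str] = []
    for rec in records:
        if rec.organism_kind not in vocab["organism_kinds"]:
            offenders.append(f"{rec.study_id}: organism_kind={rec.organism_kind!r}")
        if rec.control_design not in vocab["control_designs"]:
            offenders.append(f"{rec.study_id}: control_design={rec.control_design!r}")
        for ev in rec.environmental_variables:
            if ev not in vocab["environmental_variables"]:
                offenders.append(f"{rec.study_id}: environmental_variable={ev!r}")
        for tm in rec.traits:
            if tm.trait_category not in vocab["trait_categories"]:
                offenders.append(f"{rec.study_id}: trait_category={tm.trait_category!r}")
    if offenders:
        raise DataValidationError(
            "unknown vocabulary terms:\n  " + "\n  ".join(offenders),
            offenders=offenders,
        )


def summarize_survey(records: Sequence[SurveyRecord],
                     vocab: Mapping[str, tuple[str, ...]] | None = None,
                     validate: bool = True) -> SurveySummary:
    """Compute the survey's headline statistics.

    Studies manipulating more than one environmental variable are excluded
    from the environmental-variable breakdown only (logged), mirroring the
    convention of reporting one variable per study in that panel.  The grand
    mean of measurement occasions is the mean of per-study means, not the
    pooled mean over trait measurements, so multi-trait studies are not
    overweighted.
    """
    records = list(records)
    if not records:
        raise DataValidationError("survey table is empty")
    if validate:
        validate_records(records, vocab)

    n_studies = len(records)
    all_traits = [tm for rec in records for tm in rec.traits]
    n_meas = len(all_traits)

    def proportions(labels: Iterable[str]) -> dict[str, float]:
        s = pd.Series(list(labels))
        return (s.value_counts(normalize=True)).to_dict()

    single_var = [r for r in records if len(r.environmental_variables) == 1]
    n_excluded = n_studies - len(single_var)
    if n_excluded:
        logger.info(
            "%d multi-variable study/studies excluded from the "
            "environmental-variable breakdown only", n_excluded)

    per_study_means = {r.study_id: r.mean_timepoints for r in records}
    n_formal = sum(r.formal_quantification for r in records)

    years = pd.Series([r.year for r in records]).value_counts().sort_index()

    return SurveySummary(
        n_studies=n_studies,
        n_trait_measurements=n_meas,
        trait_category_proportions=proportions(t.trait_category for t in all_traits),
        environmental_variable_proportions=proportions(
            r.environmental_variables[0] for r in single_var),
        n_multi_variable_excluded=n_excluded,
        organism_kind_proportions=proportions(r.organism_kind for r in records),
        control_design_proportions=proportions(r.control_design for r in records),
        studies_per_year={int(y): int(n) for y, n in years.items()},
        per_study_mean_timepoints=per_study_means,
        grand_mean_timepoints=sum(per_study_means.values()) / n_studies,
        n_formal_quantification=int(n_formal),
        pct_formal_quantification=round(100.0 * n_formal / n_studies, 1),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: Canonical column names; pass ``column_map`` to adapt other headers.
SURVEY_COLUMNS = ("study_id", "year", "organism_kind", "environmental_variable",
                  "trait_category", "n_timepoints", "control_design",
                  "formal_quantification")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def read_survey_csv(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    multi_variable_sep: str = ";") -> list[SurveyRecord]:
    """Read a survey table: one row per trait measurement, study fields repeated.

    ``column_map`` maps canonical names to the file's actual headers, so
    deposits with different header conventions can be read without editing
    the file.  Multiple environmental variables are ``;``-separated within
    the cell.
    """
    df = pd.read_csv(path)
    colmap = dict(column_map or {})
    missing = [c for c in SURVEY_COLUMNS if colmap.get(c, c) not in df.columns]
    if missing:
        raise DataValidationError(
            f"survey CSV is missing column(s) {missing}; present: {list(df.columns)}")
    get = lambda c: df[colmap.get(c, c)]

    records = []
    grouped = pd.DataFrame({c: get(c) for c in SURVEY_COLUMNS}).groupby(
        "study_id", sort=False)
    for study_id, g in grouped:
        first = g.iloc[0]
        raw_flag = str(first["formal_quantification"]).strip().lower()
        if raw_flag in _TRUTHY:
            flag = True
        elif raw_flag in _FALSY:
            flag = False
        else:
            raise DataValidationError(
                f"study {study_id!r}: unreadable formal_quantification "
                f"{first['formal_quantification']!r}")
        evs = tuple(v.strip() for v in
                    str(first["environmental_variable"]).split(multi_variable_sep)
                    if v.strip())
        traits = tuple(
            TraitMeasurement(str(row["trait_category"]).strip(),
                             int(row["n_timepoints"]))
            for _, row in g.iterrows()
        )
        records.append(SurveyRecord(
            study_id=str(study_id), year=int(first["year"]),
            organism_kind=str(first["organism_kind"]).strip(),
            environmental_variables=evs, traits=traits,
            control_design=str(first["control_design"]).strip(),
            formal_quantification=flag,
        ))
    return records


def write_survey_csv(records: Sequence[SurveyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        for tm in r.traits:
            rows.append({
                "study_id": r.study_id, "year": r.year,
                "organism_kind": r.organism_kind,
                "environmental_variable": ";".join(r.environmental_variables),
                "trait_category": tm.trait_category,
                "n_timepoints": tm.n_timepoints,
                "control_design": r.control_design,
                "formal_quantification": r.formal_quantification,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
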