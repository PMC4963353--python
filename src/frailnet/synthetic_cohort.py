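"""Synthetic GP-registry and hospital-discharge generator.

The study population this package analyzes — elderly patients (75+)
classified by their general practitioners into four frailty statuses and
linked to the previous year's hospital discharge records — is privacy
restricted and not distributable.  This module generates cohorts whose
conditional prevalence structure matches the published margins (frailty by
age class and gender, hospitalization and multi-morbidity rates per status,
named multi-morbidity profile rates), so that every downstream stage of the
pipeline can be exercised and tested without access to the registry.

The sampling chain per patient is:

    gender -> age class -> frailty status -> marital & family status
           -> hospitalization -> multi-morbid vs single-category profile
           -> clinical category set -> discharge record(s)

All draws derive from a single :class:`numpy.random.Generator`, so a fixed
``(config, seed)`` pair yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import vocab

__all__ = [
    "CohortConfig",
    "CoverageError",
    "MarginTable",
    "default_config",
    "generate_cohort",
    "summarize_margins",
]

_PROB_ATOL = 1e-9


class CoverageError(RuntimeError):
    """Raised when the modality-coverage resample guard exhausts its retries."""


def _normalize(d: dict[str, float]) -> dict[str, float]:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError(f"probability row has non-positive mass: {d}")
    if abs(total - 1.0) <= 1e-12:  # idempotent: keeps round-trips exact
        return dict(d)
    return {k: v / total for k, v in d.items()}


@dataclasses.dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    Conditional probability tables are stored as plain dicts keyed by the
    vocabulary levels; rows are normalized on construction (published margins
    carry rounding error of ~1e-3).  Derived tables — the joint
    frailty-by-age-and-gender cells and the multi-morbidity rate conditional
    on hospitalization — are computed here, not stored.
    """

    n_patients: int
    seed: int
    p_gender: dict[str, float]
    p_age_given_gender: dict[str, dict[str, float]]
    p_frailty_given_age: dict[str, dict[str, float]]
    p_frailty_given_gender: dict[str, dict[str, float]]
    p_frailty_overall: dict[str, float]
    p_hosp_given_frailty: dict[str, float]
    p_multimorbid_given_frailty: dict[str, float]
    p_marital_given_frailty_gender: dict[str, dict[str, dict[str, float]]]
    p_family_given_frailty_gender: dict[str, dict[str, dict[str, float]]]
    profile_weights: dict[str, list[float]]
    other_profile_size_probs: dict[int, float]
    single_category_weights: dict
    codes_per_category: dict[str, list[str]]
    index_date: _dt.date = _dt.date(2007, 1, 1)
    window_days: int = 365
    discharges_per_patient: int = 1
    coverage_min_n: int = 5000
    max_coverage_retries: int = 5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.index_date, str):
            self.index_date = _dt.date.fromisoformat(self.index_date)
        self.p_gender = _normalize(self.p_gender)
        self.p_age_given_gender = {
            g: _normalize(row) for g, row in self.p_age_given_gender.items()
        }
        self.p_frailty_given_age = {
            a: _normalize(row) for a, row in self.p_frailty_given_age.items()
        }
        self.p_frailty_given_gender = {
            g: _normalize(row) for g, row in self.p_frailty_given_gender.items()
        }
        self.p_frailty_overall = _normalize(self.p_frailty_overall)
        self.p_marital_given_frailty_gender = {
            f: {g: _normalize(row) for g, row in per_g.items()}
            for f, per_g in self.p_marital_given_frailty_gender.items()
        }
        self.p_family_given_frailty_gender = {
            f: {g: _normalize(row) for g, row in per_g.items()}
            for f, per_g in self.p_family_given_frailty_gender.items()
        }
        self.validate()

    # -- derived tables ----------------------------------------------------

    def p_frailty_given_age_gender(self) -> dict[tuple[str, str], dict[str, float]]:
        """Joint cells via the independence-style factorization.

        The published margins give frailty by age and by gender separately;
        the default joint table is ``p(f|a,g) ∝ p(f|a)·p(f|g)/p(f)``,
        renormalized within each (age, gender) cell.
        """
        out: dict[tuple[str, str], dict[str, float]] = {}
        for a in vocab.AGE_CLASSES:
            for g in vocab.GENDERS:
                row = {
                    f: (
                        self.p_frailty_given_age[a][f]
                        * self.p_frailty_given_gender[g][f]
                        / self.p_frailty_overall[f]
                    )
                    for f in vocab.FRAILTY_STATUSES
                }
                out[(a, g)] = _normalize(row)
        return out

    def p_multimorbid_given_hosp_frailty(self) -> dict[str, float]:
        """Multi-morbidity rate conditional on hospitalization, per status."""
        out = {}
        for f in vocab.FRAILTY_STATUSES:
            hosp = self.p_hosp_given_frailty[f]
            mm = self.p_multimorbid_given_frailty[f]
            out[f] = 0.0 if hosp == 0 else min(1.0, mm / hosp)
        return out

    def single_weights_for(self, frailty: str, gender: str) -> np.ndarray:
        """Single-category weights for a stratum, overrides applied."""
        base = dict(self.single_category_weights["base"])
        for ov in self.single_category_weights.get("overrides", ()):
            if ov["frailty"] == frailty and ov["gender"] == gender:
                boosted = float(ov["weight"])
                rest = {k: v for k, v in base.items() if k != ov["category"]}
                scale = (1.0 - boosted) / sum(rest.values())
                base = {k: v * scale for k, v in rest.items()}
                base[ov["category"]] = boosted
        w = np.array([base[c] for c in vocab.CLINICAL_CATEGORIES], dtype=float)
        return w / w.sum()

    # -- validation / io ---------------------------------------------------

    def validate(self) -> None:
        for name, rows in (
            ("p_gender", [self.p_gender]),
            ("p_age_given_gender", self.p_age_given_gender.values()),
            ("p_frailty_given_age", self.p_frailty_given_age.values()),
            ("p_frailty_given_gender", self.p_frailty_given_gender.values()),
        ):
            for row in rows:
                if abs(sum(row.values()) - 1.0) > _PROB_ATOL:
                    raise ValueError(f"{name}: row does not sum to 1: {row}")
                if any(v < 0 for v in row.values()):
                    raise ValueError(f"{name}: negative probability: {row}")
        for f in vocab.FRAILTY_STATUSES:
            if not 0.0 <= self.p_hosp_given_frailty[f] <= 1.0:
                raise ValueError("p_hosp_given_frailty out of [0, 1]")
            if self.p_multimorbid_given_frailty[f] > self.p_hosp_given_frailty[f] + _PROB_ATOL:
                raise ValueError(
                    "multi-morbidity share cannot exceed hospitalization share"
                )
            if len(self.profile_weights[f]) != len(vocab.NAMED_PROFILES) + 1:
                raise ValueError("profile_weights needs one entry per named "
                                 "profile plus the residual")
            if any(w < 0 for w in self.profile_weights[f]):
                raise ValueError("profile weights must be >= 0")
        for c in vocab.CLINICAL_CATEGORIES:
            if not self.codes_per_category.get(c):
                raise ValueError(f"category {c!r} has no diagnosis codes")
        if self.discharges_per_patient < 1:
            raise ValueError("discharges_per_patient must be >= 1")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["index_date"] = self.index_date.isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def default_config(n_patients: int, seed: int) -> CohortConfig:
    """The packaged default configuration for ``n_patients`` and ``seed``.

    Pure function of its arguments: repeated calls return equal configs.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    text = resources.files("frailnet").joinpath("data/default_cohort.yaml").read_text()
    payload = yaml.safe_load(text)
    return CohortConfig(n_patients=int(n_patients), seed=int(seed), **payload)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_levels(rng, levels, prob_row, size) -> np.ndarray:
    p = np.array([prob_row[lv] for lv in levels], dtype=float)
    return rng.choice(len(levels), size=size, p=p)


def _draw_categories(rng, config, frailty, gender) -> tuple[str, ...]:
    """Category set for one hospitalized multi-morbid patient."""
    weights = np.asarray(config.profile_weights[frailty], dtype=float)
    weights = weights / weights.sum()
    k = int(rng.choice(len(weights), p=weights))
    if k < len(vocab.NAMED_PROFILES):
        return tuple(sorted(vocab.NAMED_PROFILES[k][1]))
    sizes = sorted(config.other_profile_size_probs)
    p_sizes = np.array([config.other_profile_size_probs[s] for s in sizes], float)
    size = int(rng.choice(sizes, p=p_sizes / p_sizes.sum()))
    w = config.single_weights_for(frailty, gender)
    idx = rng.choice(len(vocab.CLINICAL_CATEGORIES), size=size, replace=False, p=w)
    return tuple(sorted(vocab.CLINICAL_CATEGORIES[i] for i in idx))


def _coverage_ok(registry: pd.DataFrame, categories_seen: set[str],
                 config: CohortConfig) -> bool:
    for col, levels in (
        ("age_class", vocab.AGE_CLASSES),
        ("gender", vocab.GENDERS),
        ("marital_status", vocab.MARITAL_STATUSES),
        ("family_status", vocab.FAMILY_STATUSES),
        ("frailty_status", vocab.FRAILTY_STATUSES),
    ):
        if set(registry[col].unique()) != set(levels):
            return False
    if any(config.p_hosp_given_frailty[f] > 0 for f in vocab.FRAILTY_STATUSES):
        if categories_seen != set(vocab.CLINICAL_CATEGORIES):
            return False
    return True


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a registry and its discharge table from ``config``.

    Returns ``(registry, discharges)``.  The registry carries the generator's
    own draw log in ``registry.attrs["drawn_categories"]`` (patient id ->
    sorted category tuple), which serves as the linkage round-trip oracle.

    For cohorts of at least ``config.coverage_min_n`` patients a resample
    guard re-draws the whole cohort (deterministically, from the seed) until
    every reachable modality occurs at least once; exhausting the retry
    budget raises :class:`CoverageError` and signals a degenerate config.
    """
    n = config.n_patients
    last_missing = None
    for attempt in range(config.max_coverage_retries):
        rng = np.random.default_rng([config.seed, attempt])
        registry, discharges, drawn = _generate_once(rng, config)
        seen = set()
        for cats in drawn.values():
            seen.update(cats)
        if n < config.coverage_min_n or _coverage_ok(registry, seen, config):
            registry.attrs["drawn_categories"] = drawn
            registry.attrs["seed"] = config.seed
            registry.attrs["attempt"] = attempt
            return registry, discharges
        last_missing = (set(vocab.CLINICAL_CATEGORIES) - seen) or "socio-demographic level"
    raise CoverageError(
        f"modality coverage not reached after {config.max_coverage_retries} "
        f"resamples (missing: {last_missing}); the configuration is degenerate"
    )


def _generate_once(rng, config: CohortConfig):
    n = config.n_patients
    gender_idx = _sample_levels(rng, vocab.GENDERS, config.p_gender, n)

    age_idx = np.zeros(n, dtype=int)
    for gi, g in enumerate(vocab.GENDERS):
        mask = gender_idx == gi
        if mask.any():
            age_idx[mask] = _sample_levels(
                rng, vocab.AGE_CLASSES, config.p_age_given_gender[g], int(mask.sum())
            )

    joint = config.p_frailty_given_age_gender()
    frailty_idx = np.zeros(n, dtype=int)
    for ai, a in enumerate(vocab.AGE_CLASSES):
        for gi, g in enumerate(vocab.GENDERS):
            mask = (age_idx == ai) & (gender_idx == gi)
            if mask.any():
                frailty_idx[mask] = _sample_levels(
                    rng, vocab.FRAILTY_STATUSES, joint[(a, g)], int(mask.sum())
                )

    marital_idx = np.zeros(n, dtype=int)
    family_idx = np.zeros(n, dtype=int)
    for fi, f in enumerate(vocab.FRAILTY_STATUSES):
        for gi, g in enumerate(vocab.GENDERS):
            mask = (frailty_idx == fi) & (gender_idx == gi)
            if not mask.any():
                continue
            m = int(mask.sum())
            marital_idx[mask] = _sample_levels(
                rng, vocab.MARITAL_STATUSES,
                config.p_marital_given_frailty_gender[f][g], m)
            family_idx[mask] = _sample_levels(
                rng, vocab.FAMILY_STATUSES,
                config.p_family_given_frailty_gender[f][g], m)

    p_hosp = np.array([config.p_hosp_given_frailty[f] for f in vocab.FRAILTY_STATUSES])
    hospitalized = rng.random(n) < p_hosp[frailty_idx]

    p_mm_hosp = config.p_multimorbid_given_hosp_frailty()
    p_mm = np.array([p_mm_hosp[f] for f in vocab.FRAILTY_STATUSES])
    multimorbid = np.zeros(n, dtype=bool)
    multimorbid[hospitalized] = (
        rng.random(int(hospitalized.sum())) < p_mm[frailty_idx[hospitalized]]
    )

    width = max(6, len(str(n)))
    ids = np.array([f"P{i:0{width}d}" for i in range(n)])

    registry = pd.DataFrame(
        {
            "patient_id": ids,
            "age_class": np.array(vocab.AGE_CLASSES, dtype=object)[age_idx],
            "gender": np.array(vocab.GENDERS, dtype=object)[gender_idx],
            "marital_status": np.array(vocab.MARITAL_STATUSES, dtype=object)[marital_idx],
            "family_status": np.array(vocab.FAMILY_STATUSES, dtype=object)[family_idx],
            "frailty_status": np.array(vocab.FRAILTY_STATUSES, dtype=object)[frailty_idx],
        }
    )

    drawn: dict[str, tuple[str, ...]] = {}
    rows = []
    for i in np.flatnonzero(hospitalized):
        f = vocab.FRAILTY_STATUSES[frailty_idx[i]]
        g = vocab.GENDERS[gender_idx[i]]
        if multimorbid[i]:
            cats = _draw_categories(rng, config, f, g)
        else:
            w = config.single_weights_for(f, g)
            cats = (vocab.CLINICAL_CATEGORIES[int(rng.choice(len(w), p=w))],)
        drawn[ids[i]] = cats
        codes = []
        for c in cats:
            roots = config.codes_per_category[c]
            root = roots[int(rng.integers(len(roots)))]
            codes.append(f"{root}.{int(rng.integers(10))}")
        n_dis = min(config.discharges_per_patient, len(codes))
        buckets: list[list[str]] = [[] for _ in range(n_dis)]
        for j, code in enumerate(codes):
            buckets[j % n_dis].append(code)
        for bucket in buckets:
            offset = int(rng.integers(1, config.window_days + 1))
            date = config.index_date - _dt.timedelta(days=offset)
            rows.append((ids[i], date.isoformat(), ";".join(bucket)))

    discharges = pd.DataFrame(rows, columns=["patient_id", "date", "codes"])
    return registry, discharges, drawn


# ---------------------------------------------------------------------------
# margins
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MarginTable:
    """Prevalence margins of a generated (or linked) cohort, in percent."""

    n_patients: int
    counts_by_status: pd.Series
    prevalence_overall: pd.Series           # % of cohort per frailty status
    prevalence_by_gender: pd.DataFrame      # % within gender
    prevalence_by_age: pd.DataFrame         # % within age class
    gender_ratio: pd.Series                 # M/F count ratio per status (NaN if no F)
    hospitalization: pd.Series              # % hospitalized within status
    multimorbidity: pd.Series               # % multi-morbid within status

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "overall_prevalence_pct": self.prevalence_overall,
            "hospitalization_pct": self.hospitalization,
            "multimorbidity_pct": self.multimorbidity,
            "gender_ratio_MF": self.gender_ratio,
        }
        return pd.DataFrame(rows).T


def summarize_margins(
    registry: pd.DataFrame,
    discharges: pd.DataFrame,
    category_map=None,
) -> MarginTable:
    """Empirical analogue of the published prevalence table.

    Multi-morbidity requires grouping discharge codes into categories; by
    default the packaged toy code map is used (pass ``category_map`` when the
    cohort was generated with custom code lists).
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    from .record_linkage import CategoryMap, group_codes

    if category_map is None:
        category_map = CategoryMap.default()

    statuses = list(vocab.FRAILTY_STATUSES)
    frailty = registry["frailty_status"]
    counts = frailty.value_counts().reindex(statuses, fill_value=0)
    overall = counts / len(registry) * 100.0

    by_gender = pd.DataFrame(index=list(vocab.GENDERS), columns=statuses, dtype=float)
    for g in vocab.GENDERS:
        sub = registry[registry["gender"] == g]
        if len(sub):
            by_gender.loc[g] = (
                sub["frailty_status"].value_counts().reindex(statuses, fill_value=0)
                / len(sub) * 100.0
            )

    by_age = pd.DataFrame(index=list(vocab.AGE_CLASSES), columns=statuses, dtype=float)
    for a in vocab.AGE_CLASSES:
        sub = registry[registry["age_class"] == a]
        if len(sub):
            by_age.loc[a] = (
                sub["frailty_status"].value_counts().reindex(statuses, fill_value=0)
                / len(sub) * 100.0
            )

    ratio = {}
    for f in statuses:
        sub = registry[frailty == f]
        n_m = int((sub["gender"] == "Male").sum())
        n_f = int((sub["gender"] == "Female").sum())
        ratio[f] = np.nan if n_f == 0 else n_m / n_f
    ratio = pd.Series(ratio)

    cats_per_patient: dict[str, set[str]] = {}
    for pid, codes in zip(discharges["patient_id"], discharges["codes"]):
        code_list = codes.split(";") if isinstance(codes, str) else list(codes)
        cats_per_patient.setdefault(pid, set()).update(
            group_codes(code_list, category_map)
        )

    hosp = pd.Series(0.0, index=statuses)
    mm = pd.Series(0.0, index=statuses)
    hosp_ids = set(discharges["patient_id"])
    for f in statuses:
        sub = registry[frailty == f]
        if len(sub) == 0:
            hosp[f] = np.nan
            mm[f] = np.nan
            continue
        ids = sub["patient_id"]
        hosp[f] = ids.isin(hosp_ids).mean() * 100.0
        mm[f] = np.mean([len(cats_per_patient.get(pid, ())) >= 2 for pid in ids]) * 100.0

    return MarginTable(
        n_patients=len(registry),
        counts_by_status=counts,
        prevalence_overall=overall,
        prevalence_by_gender=by_gender,
        prevalence_by_age=by_age,
        gender_ratio=ratio,
        hospitalization=hosp,
        multimorbidity=mm,
    )
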