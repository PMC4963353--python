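"""Deterministic linkage of hospital discharges to the GP registry.

Linkage is an exact join on the de-identified patient code.  Discharge
diagnoses (ICD-9-CM style code strings, main and secondary treated alike)
are grouped into clinical categories by longest-prefix match against a
root -> category map, and collapsed per patient into dichotomous
presence/absence flags.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import pandas as pd

from . import vocab

__all__ = ["CategoryMap", "FeatureTable", "group_codes", "link"]


@dataclasses.dataclass(frozen=True)
class CategoryMap:
    """Mapping from ICD-9-CM code roots to clinical category names.

    Roots are matched as string prefixes after stripping the decimal point,
    longest root first, so a map may mix 3-digit chapter roots with more
    specific subcodes.
    """

    entries: dict[str, str]
    vocabulary: tuple[str, ...] = vocab.CLINICAL_CATEGORIES

    def __post_init__(self) -> None:
        allowed = set(self.vocabulary)
        for root, category in self.entries.items():
            if category not in allowed:
                raise ValueError(
                    f"category {category!r} (root {root!r}) is not in the "
                    f"configured vocabulary"
                )

    @classmethod
    def default(cls) -> "CategoryMap":
        """Map built from the packaged toy code lists."""
        from .synthetic_cohort import default_config

        config = default_config(1, 0)
        entries = {
            root: cat
            for cat, roots in config.codes_per_category.items()
            for root in roots
        }
        return cls(entries=entries)

    @classmethod
    def from_file(cls, path, sep: str = ",", vocabulary=None) -> "CategoryMap":
        df = pd.read_csv(path, sep=sep, dtype=str)
        if list(df.columns[:2]) != ["root", "category"]:
            df.columns = ["root", "category"] + list(df.columns[2:])
        entries = dict(zip(df["root"], df["category"]))
        if vocabulary is None:
            vocabulary = vocab.CLINICAL_CATEGORIES
            if not set(entries.values()) <= set(vocabulary):
                vocabulary = tuple(sorted(set(entries.values())))
        return cls(entries=entries, vocabulary=tuple(vocabulary))

    def to_file(self, path, sep: str = ",") -> None:
        pd.DataFrame(
            sorted(self.entries.items()), columns=["root", "category"]
        ).to_csv(path, sep=sep, index=False)

    def lookup(self, code: str) -> str | None:
        """Longest-prefix category for one code, or None when unmatched."""
        normalized = code.strip().replace(".", "")
        for root in sorted(self.entries, key=len, reverse=True):
            if normalized.startswith(root.replace(".", "")):
                return self.entries[root]
        return None


def group_codes(codes, category_map: CategoryMap, unmatched: list | None = None):
    """Collapse a code list into the set of matched clinical categories.

    Unmatched codes are not an error; pass a list as ``unmatched`` to collect
    them (the caller decides whether to log or count).
    """
    out: set[str] = set()
    for code in codes:
        category = category_map.lookup(code)
        if category is None:
            if unmatched is not None:
                unmatched.append(code)
        else:
            out.add(category)
    return out


class FeatureTable(pd.DataFrame):
    """Per-patient analysis table: modalities + dichotomous disease flags.

    A thin DataFrame subclass so linkage metadata (unlinked discharge count,
    unmatched code list) survives as regular attributes.
    """

    _metadata = ["unlinked_discharge_count", "unmatched_codes", "category_names"]

    @property
    def _constructor(self):
        return FeatureTable


def link(
    registry: pd.DataFrame,
    discharges: pd.DataFrame,
    category_map: CategoryMap | None = None,
    window: tuple[_dt.date, _dt.date] | None = None,
) -> FeatureTable:
    """Join discharges onto the registry and emit the flag table.

    Parameters
    ----------
    registry, discharges
        As produced by :func:`frailnet.synthetic_cohort.generate_cohort` or
        read back from their delimited-text forms.  ``discharges.codes`` may
        be ``;``-joined strings or lists.
    category_map
        Root -> category map; defaults to the packaged toy map.
    window
        Half-open date interval ``[start, end)``; discharges outside it are
        excluded before linkage.  ``None`` keeps every discharge.

    Returns
    -------
    FeatureTable
        One row per registry patient (row order preserved) with columns
        ``patient_id``, the four socio-demographic modalities,
        ``frailty_status``, ``hospitalized`` and one boolean column per
        clinical category.  Discharges whose id is absent from the registry
        are excluded and counted in ``unlinked_discharge_count``.
    """
    if registry["patient_id"].duplicated().any():
        dupes = registry.loc[registry["patient_id"].duplicated(), "patient_id"]
        raise ValueError(
            f"duplicate patient ids in registry (e.g. {dupes.iloc[0]!r}); "
            "the de-identification contract guarantees uniqueness"
        )
    if category_map is None:
        category_map = CategoryMap.default()

    known = set(registry["patient_id"])
    unmatched_codes: list[str] = []
    unlinked = 0
    cats_per_patient: dict[str, set[str]] = {}
    linked_ids: set[str] = set()

    for pid, date, codes in zip(
        discharges["patient_id"], discharges["date"], discharges["codes"]
    ):
        if window is not None:
            d = _dt.date.fromisoformat(str(date)[:10])
            if not (window[0] <= d < window[1]):
                continue
        if pid not in known:
            unlinked += 1
            continue
        linked_ids.add(pid)
        code_list = codes.split(";") if isinstance(codes, str) else list(codes)
        cats_per_patient.setdefault(pid, set()).update(
            group_codes(code_list, category_map, unmatched_codes)
        )

    table = FeatureTable(registry.copy().reset_index(drop=True))
    table["hospitalized"] = table["patient_id"].map(lambda p: p in linked_ids)
    categories = tuple(vocab.CLINICAL_CATEGORIES)
    for c in categories:
        table[c] = table["patient_id"].map(
            lambda p, c=c: c in cats_per_patient.get(p, ())
        )
    table.unlinked_discharge_count = unlinked
    table.unmatched_codes = unmatched_codes
    table.category_names = categories
    return table
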