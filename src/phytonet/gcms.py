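"""GC/MS composition analytics.

Turns an identified peak table plus an n-alkane retention ladder into a
composition report: temperature-programmed (van den Dool-Kratz) retention
indices, identity confirmation against literature indices, area-percent
class subtotals over a controlled chemical-class vocabulary, and
profile-to-profile comparisons (per-compound deltas, grouped isomers,
absence flags).
"""
from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .exceptions import OutOfRangeError, ValidationError

__all__ = [
    "AlkaneLadder",
    "ChromatogramPeak",
    "CompositionSummary",
    "retention_index",
    "confirm_identity",
    "summarize_composition",
    "compare_profiles",
    "normalize_chemical_class",
    "MONOTERPENE_HYDROCARBON",
    "OXYGENATED_MONOTERPENE",
    "SESQUITERPENE_HYDROCARBON",
    "OXYGENATED_SESQUITERPENE",
    "OTHER",
    "CLASS_VOCABULARY",
    "DEFAULT_RI_TOLERANCE",
]

#: Default window for RI-based identity confirmation on 5%-phenyl columns.
DEFAULT_RI_TOLERANCE = 10.0

MONOTERPENE_HYDROCARBON = "monoterpene hydrocarbon"
OXYGENATED_MONOTERPENE = "oxygenated monoterpene"
SESQUITERPENE_HYDROCARBON = "sesquiterpene hydrocarbon"
OXYGENATED_SESQUITERPENE = "oxygenated sesquiterpene"
OTHER = "other"

CLASS_VOCABULARY = (
    MONOTERPENE_HYDROCARBON,
    OXYGENATED_MONOTERPENE,
    SESQUITERPENE_HYDROCARBON,
    OXYGENATED_SESQUITERPENE,
    OTHER,
)

_OXY_TOKENS = ("alcohol", "oxide", "epoxide", "ketone", "aldehyde", "phenol",
               "acetate", "oxygenated", "ether", "ester")


def normalize_chemical_class(label: str) -> str:
    """Map a free-text chemical-class description onto the controlled
    vocabulary.

    Skeleton descriptors (bicyclic, aromatic, monocyclic, tricyclic, acyclic)
    collapse into the parent class: any monoterpene hydrocarbon - aromatic
    included - counts as ``monoterpene hydrocarbon``; alcohols, oxides and
    other oxygen-bearing terpenes count as the oxygenated class. Non-terpene
    labels such as fatty acid esters map to ``other``. Unrecognized labels
    raise :class:`ValidationError`.
    """
    s = " ".join(str(label).lower().replace("-", " ").split())
    if s in CLASS_VOCABULARY:
        return s
    # tolerate missing spaces in descriptors ("monocyclicmonoterpene")
    if "sesquiterpen" in s:
        if "hydrocarbon" in s:
            return SESQUITERPENE_HYDROCARBON
        if any(tok in s for tok in _OXY_TOKENS):
            return OXYGENATED_SESQUITERPENE
    elif "monoterpen" in s:
        if "hydrocarbon" in s:
            return MONOTERPENE_HYDROCARBON
        if any(tok in s for tok in _OXY_TOKENS):
            return OXYGENATED_MONOTERPENE
    elif any(tok in s for tok in ("fatty acid", "ester", "alkane",
                                  "unknown", "unclassified")):
        return OTHER
    raise ValidationError(f"unrecognized chemical class: {label!r}")


# ---------------------------------------------------------------------------
# retention indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlkaneLadder:
    """Homologous n-alkane calibration series: (carbon number, rt in min),
    both strictly increasing."""

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self):
        cn = tuple(int(c) for c in self.carbon_numbers)
        rt = tuple(float(t) for t in self.retention_times)
        if len(cn) != len(rt) or len(cn) < 2:
            raise ValidationError("ladder needs >= 2 aligned entries")
        if any(b <= a for a, b in zip(cn, cn[1:])):
            raise ValidationError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValidationError("retention times must be strictly increasing")
        object.__setattr__(self, "carbon_numbers", cn)
        object.__setattr__(self, "retention_times", rt)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[int, float]]) -> "AlkaneLadder":
        cn, rt = zip(*entries)
        return cls(tuple(cn), tuple(rt))

    @property
    def entries(self) -> list[tuple[int, float]]:
        return list(zip(self.carbon_numbers, self.retention_times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon_number": self.carbon_numbers,
                             "rt": self.retention_times})

    def retention_index(self, rt: float) -> float:
        return retention_index(rt, self)


def retention_index(rt_analyte: float, ladder: AlkaneLadder) -> float:
    """Temperature-programmed retention index by linear interpolation between
    the bracketing n-alkanes.

    RI = 100 * (n_i + (n_j - n_i) * (t - t_i) / (t_j - t_i)) for the alkane
    pair (i, j) bracketing the analyte. Analytes eluting outside the ladder
    span raise :class:`OutOfRangeError`; no extrapolation is performed.
    """
    rts = np.asarray(ladder.retention_times)
    cns = np.asarray(ladder.carbon_numbers, dtype=float)
    t = float(rt_analyte)
    if t < rts[0] or t > rts[-1]:
        raise OutOfRangeError(
            f"rt {t} min outside ladder span [{rts[0]}, {rts[-1]}]")
    i = int(np.searchsorted(rts, t, side="right")) - 1
    if i == len(rts) - 1:  # exactly the last alkane
        return 100.0 * cns[-1]
    frac = (t - rts[i]) / (rts[i + 1] - rts[i])
    return float(100.0 * (cns[i] + (cns[i + 1] - cns[i]) * frac))


def confirm_identity(ri_exp: float, ri_lit: float,
                     tolerance: float = DEFAULT_RI_TOLERANCE,
                     ) -> tuple[bool, float]:
    """RI cross-check: confirmed iff |RI_exp - RI_lit| <= tolerance.

    Returns ``(confirmed, signed deviation RI_exp - RI_lit)``.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    deviation = float(ri_exp) - float(ri_lit)
    return abs(deviation) <= tolerance, deviation


# ---------------------------------------------------------------------------
# composition summaries
# ---------------------------------------------------------------------------

@dataclass
class ChromatogramPeak:
    """One identified chromatogram peak."""

    peak_id: int
    rt: float
    name: str
    chemical_class: str
    area_pct: float
    ri_exp: float | None = None
    ri_lit: float | None = None

    def __post_init__(self):
        if self.rt <= 0:
            raise ValidationError(f"peak {self.peak_id}: rt must be positive")
        if self.area_pct < 0:
            raise ValidationError(
                f"peak {self.peak_id}: area_pct must be non-negative")


@dataclass
class CompositionSummary:
    """Per-class area-percent subtotals plus grand totals.

    ``total_identified`` sums every identified peak; ``classified_total``
    sums the four terpene classes only (excluding ``other``), which is how
    chromatography tables typically print their footer.
    """

    table: pd.DataFrame
    class_totals: dict[str, float]
    total_identified: float
    classified_total: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {k: round_half_up(v, ndigits) for k, v in self.class_totals.items()}
        out["total_identified"] = round_half_up(self.total_identified, ndigits)
        out["classified_total"] = round_half_up(self.classified_total, ndigits)
        return out

    def report(self) -> str:
        lines = [self.table.to_string(index=False), ""]
        for cls in CLASS_VOCABULARY:
            lines.append(f"{cls:<28}{round_half_up(self.class_totals[cls]):>8.2f}")
        lines.append(f"{'total (terpene classes)':<28}"
                     f"{round_half_up(self.classified_total):>8.2f}")
        lines.append(f"{'total identified':<28}"
                     f"{round_half_up(self.total_identified):>8.2f}")
        return "\n".join(lines)


def summarize_composition(peaks: Sequence[ChromatogramPeak]) -> CompositionSummary:
    """Class subtotals and totals over an identified peak list.

    Class labels are normalized onto the controlled vocabulary first; an
    unknown label raises :class:`ValidationError`. Subtotals are computed at
    full precision (round only for display).
    """
    if not peaks:
        raise ValidationError("empty peak list")
    rows = []
    for p in peaks:
        rows.append({
            "peak_id": p.peak_id, "rt": p.rt, "name": p.name,
            "chemical_class": normalize_chemical_class(p.chemical_class),
            "ri_exp": p.ri_exp, "ri_lit": p.ri_lit, "area_pct": p.area_pct,
        })
    table = pd.DataFrame(rows).sort_values("rt", kind="stable").reset_index(drop=True)
    totals = {cls: float(table.loc[table.chemical_class == cls, "area_pct"].sum())
              for cls in CLASS_VOCABULARY}
    total = float(table.area_pct.sum())
    classified = total - totals[OTHER]
    return CompositionSummary(table=table, class_totals=totals,
                              total_identified=total,
                              classified_total=classified)


# ---------------------------------------------------------------------------
# profile comparison
# ---------------------------------------------------------------------------

def _norm_name(name: str) -> str:
    s = unicodedata.normalize("NFKC", str(name)).strip().lower()
    s = s.replace("−", "-").replace("–", "-").replace("—", "-")
    s = re.sub(r"\s*\([^()]*\)\s*$", "", s)  # drop a trailing synonym "(...)"
    return re.sub(r"\s+", " ", s).strip()


def compare_profiles(current: CompositionSummary | Sequence[ChromatogramPeak],
                     reference: Sequence[tuple[str, float]],
                     groups: Mapping[str, Sequence[str]] | None = None,
                     ) -> pd.DataFrame:
    """Per-compound area-percent deltas between a current profile and a
    reference profile.

    Compound names match case-insensitively after synonym normalization
    (trailing parenthetical synonyms are ignored). ``groups`` maps a group
    label (e.g. a pair of enantiomers) to its member compound names; the
    group's current value is the members' sum and is compared against a
    reference entry carrying the group label, reported as a ``grouped`` row.
    Compounds present on one side only are flagged ``absent_in_current`` /
    ``absent_in_reference``.
    """
    if isinstance(current, CompositionSummary):
        cur_table = current.table
    else:
        cur_table = summarize_composition(current).table
    cur: dict[str, float] = {}
    cur_names: dict[str, str] = {}
    for _, row in cur_table.iterrows():
        key = _norm_name(row["name"])
        cur[key] = cur.get(key, 0.0) + float(row["area_pct"])
        cur_names.setdefault(key, str(row["name"]))
    ref = {_norm_name(n): (n, float(v)) for n, v in reference}
    groups = {k: tuple(v) for k, v in (groups or {}).items()}
    grouped_members = {_norm_name(m) for ms in groups.values() for m in ms}

    rows = []
    seen_ref = set()
    for key, value in cur.items():
        if key in grouped_members:
            continue
        if key in ref:
            ref_name, ref_val = ref[key]
            rows.append({"name": ref_name, "current_pct": value,
                         "reference_pct": ref_val, "delta_pct": value - ref_val,
                         "status": "shared"})
            seen_ref.add(key)
        else:
            rows.append({"name": cur_names[key], "current_pct": value,
                         "reference_pct": np.nan, "delta_pct": np.nan,
                         "status": "absent_in_reference"})
    for label, members in groups.items():
        combined = sum(cur.get(_norm_name(m), 0.0) for m in members)
        gkey = _norm_name(label)
        if gkey in ref:
            ref_name, ref_val = ref[gkey]
            seen_ref.add(gkey)
            rows.append({"name": label, "current_pct": combined,
                         "reference_pct": ref_val,
                         "delta_pct": combined - ref_val, "status": "grouped"})
        else:
            rows.append({"name": label, "current_pct": combined,
                         "reference_pct": np.nan, "delta_pct": np.nan,
                         "status": "grouped"})
    for key, (ref_name, ref_val) in ref.items():
        if key not in seen_ref:
            rows.append({"name": ref_name, "current_pct": np.nan,
                         "reference_pct": ref_val, "delta_pct": np.nan,
                         "status": "absent_in_current"})
    return pd.DataFrame(rows).reset_index(drop=True)
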