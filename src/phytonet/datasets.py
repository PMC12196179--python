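"""Bundled reference measurements for *Melaleuca quinquenervia* leaf
essential oil (MQLEO).

These small tables — a GC/MS composition profile, a cytotoxicity panel, the
hub-target centrality table of a STRING-derived PPI screen, compound-target
degree scores, and Annexin/PI quadrant percentages — are published study
measurements of the Egyptian leaf oil, carried as plain data for worked
examples and for validating the report arithmetic. They are inputs to the
pipeline, not outputs of this package.
"""
from __future__ import annotations

import pandas as pd

from .gcms import ChromatogramPeak

__all__ = [
    "leaf_oil_composition",
    "leaf_oil_peaks",
    "cytotoxicity_panel",
    "hub_centralities",
    "compound_degree_scores",
    "apoptosis_quadrants",
    "reference_profile_1991",
    "ALPHA_PINENE_GROUP",
    "PUBLISHED_TIER2_THRESHOLDS",
    "DOCKED_TARGETS",
]

# GC/MS peak table: (peak_id, rt_min, name, chemical class as annotated,
# RI_exp, RI_lit, area %)
_COMPOSITION = (
    (1, 3.540, "Methyl 2-methylbutyrate (Butanoic acid, 2-methyl-, methyl ester)",
     "Fatty acid ester", 769, 767, 0.04),
    (2, 7.565, "1R-α-Pinene (D-α-Pinene)",
     "Bicyclic monoterpene hydrocarbon", 923, 922, 15.97),
    (3, 8.725, "1S-α-Pinene (L-α-Pinene)",
     "Bicyclic monoterpene hydrocarbon", 962, 963, 5.29),
    (4, 10.075, "m-Cymene", "Aromatic monoterpene hydrocarbon", 1006, 1005, 1.54),
    (5, 10.305, "1,8-Cineole (Eucalyptol)",
     "Monocyclic monoterpene oxide", 1013, 1013, 31.57),
    (6, 10.370, "(+)-3-Carene", "Aromatic monoterpene hydrocarbon", 1015, 1015, 11.57),
    (7, 11.230, "γ-Terpinene", "Monocyclic monoterpene hydrocarbon", 1043, 1042, 0.58),
    (8, 12.750, "Fenchol", "Monocyclic monoterpene alcohol", 1091, 1097, 0.24),
    (9, 14.275, "Isoborneol", "Bicyclic monoterpene alcohol", 1141, 1147, 0.48),
    (10, 14.680, "Terpinen-4-ol", "Monocyclic monoterpene alcohol", 1154, 1152, 0.80),
    (11, 14.950, "trans-Verbenol", "Bicyclic monoterpene alcohol", 1163, 1155, 0.11),
    (12, 15.065, "trans-Ocimenol", "Acyclic monoterpene alcohol", 1167, 1169, 8.26),
    (13, 22.955, "α-Guaiene", "Bicyclic sesquiterpene hydrocarbon", 1445, 1440, 0.16),
    (14, 23.860, "(+)-Ledene", "Bicyclic sesquiterpene hydrocarbon", 1480, 1482, 0.24),
    (15, 25.590, "(−)-Palustrol", "Bicyclic sesquiterpene alcohol", 1561, 1562, 0.56),
    (16, 25.795, "Caryophyllene oxide", "Tricyclic sesquiterpene oxide", 1572, 1578, 2.23),
    (17, 25.930, "(−)-Globulol", "Tricyclic sesquiterpene alcohol", 1578, 1580, 0.25),
    (18, 26.135, "Viridiflorol", "Tricyclic sesquiterpene alcohol", 1589, 1587, 13.65),
    (19, 26.390, "Ledol", "Tricyclic sesquiterpene alcohol", 1601, 1599, 4.55),
)

#: α-pinene enantiomers reported jointly in profile comparisons.
ALPHA_PINENE_GROUP = {
    "α-pinene isomers": ("1R-α-Pinene (D-α-Pinene)", "1S-α-Pinene (L-α-Pinene)")
}

#: The four hub targets taken into docking, in degree order.
DOCKED_TARGETS = ("ESR1", "CASP3", "PPARG", "PTGS2")

#: Tier-2 thresholds as recorded by the original PPI screen.
PUBLISHED_TIER2_THRESHOLDS = {"bc_min": 1394.17, "cc_min": 0.246, "dc_min": 43}


def leaf_oil_composition() -> pd.DataFrame:
    """The 19-peak MQLEO composition table (retention data, class, area %)."""
    return pd.DataFrame(
        _COMPOSITION,
        columns=["peak_id", "rt", "name", "chemical_class", "ri_exp",
                 "ri_lit", "area_pct"])


def leaf_oil_peaks() -> list[ChromatogramPeak]:
    """The composition table as :class:`ChromatogramPeak` records."""
    return [ChromatogramPeak(peak_id=p, rt=rt, name=n, chemical_class=cls,
                             area_pct=a, ri_exp=ri_e, ri_lit=ri_l)
            for p, rt, n, cls, ri_e, ri_l, a in _COMPOSITION]


def cytotoxicity_panel() -> pd.DataFrame:
    """CC50 (VERO) and IC50 values (ug/mL, mean and SD) for the oil and the
    staurosporine positive control."""
    rows = [
        ("MQLEO", "VERO", 77.76, 3.96, True),
        ("MQLEO", "MCF-7", 27.74, 1.41, False),
        ("MQLEO", "HepG-2", 66.04, 3.36, False),
        ("MQLEO", "A-549", 18.09, 0.92, False),
        ("Staurosporine", "VERO", 24.20, 1.23, True),
        ("Staurosporine", "MCF-7", 4.62, 0.24, False),
        ("Staurosporine", "HepG-2", 9.51, 0.48, False),
        ("Staurosporine", "A-549", 3.92, 0.20, False),
    ]
    return pd.DataFrame(rows, columns=["agent", "cell_line", "c50", "sd",
                                       "is_normal_line"])


def hub_centralities() -> pd.DataFrame:
    """Centrality table of the 19 core PPI hub targets (BC raw pair counts,
    CC normalized closeness, DC degree), indexed by gene symbol."""
    rows = [
        ("ESR1", 8287.888526, 0.26860565, 99),
        ("CASP3", 4448.232593, 0.2670068, 93),
        ("PPARG", 5617.635482, 0.2652027, 88),
        ("PTGS2", 5493.159146, 0.26430976, 85),
        ("HSP90AA1", 3015.111312, 0.26079734, 82),
        ("MMP9", 3298.324704, 0.25950413, 82),
        ("GSK3B", 3013.523609, 0.26036484, 71),
        ("HSP90AB1", 1607.859991, 0.25570033, 69),
        ("SIRT1", 2215.048411, 0.25737705, 68),
        ("APP", 3729.932474, 0.25632653, 63),
        ("KDR", 2429.196004, 0.25220884, 57),
        ("ICAM1", 1813.331077, 0.25445705, 56),
        ("CYP3A4", 2092.784051, 0.25160256, 55),
        ("ACE", 2263.673069, 0.25322581, 54),
        ("NR3C1", 2162.884329, 0.25570033, 54),
        ("PPARA", 2315.896888, 0.25160256, 52),
        ("MAOA", 2097.54489, 0.25039872, 51),
        ("MAOB", 1518.447362, 0.24666143, 48),
        ("MAPK14", 1912.303096, 0.24782952, 45),
    ]
    return (pd.DataFrame(rows, columns=["node", "bc", "cc", "dc"])
            .set_index("node"))


def compound_degree_scores() -> pd.Series:
    """Compound-target network degree scores of the 19 oil constituents."""
    rows = [
        ("Methyl 2-methylbutyrate", 169),
        ("m-Cymene", 169),
        ("trans-Verbenol", 154),
        ("γ-Terpinene", 146),
        ("Fenchol", 143),
        ("1R-α-Pinene", 141),
        ("1S-α-Pinene", 141),
        ("Terpinen-4-ol", 139),
        ("Isoborneol", 134),
        ("1,8-Cineole (Eucalyptol)", 133),
        ("(+)-3-Carene", 129),
        ("α-Guaiene", 127),
        ("trans-Ocimenol", 120),
        ("(−)-Palustrol", 101),
        ("(−)-Globulol", 98),
        ("Viridiflorol", 98),
        ("Ledol", 98),
        ("Caryophyllene oxide", 97),
        ("(+)-Ledene", 96),
    ]
    s = pd.Series(dict(rows), name="degree")
    s.index.name = "compound"
    return s


def apoptosis_quadrants() -> dict[str, tuple[float, float, float, float]]:
    """Annexin/PI quadrant percentages (viable, early, late, necrotic) for
    oil-treated and control A549 cells."""
    return {
        "treated": (72.39, 15.02, 9.30, 3.29),
        "control": (97.39, 0.52, 0.18, 1.91),
    }


def reference_profile_1991() -> list[tuple[str, float]]:
    """Major-constituent area percentages from the 1991 Egyptian leaf-oil
    analysis, used as the historical comparison profile."""
    return [
        ("1,8-Cineole", 57.2),
        ("α-Terpineol", 13.2),
        ("α-pinene isomers", 6.2),
    ]
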