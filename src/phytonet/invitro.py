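"""Quantitative reduction of in vitro readouts.

Covers MTT viability normalization, four-parameter logistic (4PL)
dose-response fitting for IC50/CC50 and arbitrary inhibition levels,
selectivity-index and NCI activity classification, Annexin V/PI quadrant
quantification with death fold-change, cell-cycle phase gating, wound-closure
metrics, and Welch two-group comparison.

The 4PL fit follows the statsmodels convention: a :class:`FourPL` model is
built from data and ``fit()`` returns a :class:`FourPLResults` object that
carries estimates, uncertainties, diagnostics and a ``summary()`` table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from ._utils import round_half_up
from .exceptions import FitError, ValidationError

__all__ = [
    "DoseResponse",
    "FourPL",
    "FourPLResults",
    "fit_4pl",
    "viability_percent",
    "selectivity_index",
    "nci_classify",
    "cytotoxicity_profile",
    "FlowEventSet",
    "QuadrantFractions",
    "quadrant_fractions",
    "DeathSummary",
    "death_summary",
    "CellCycleHistogram",
    "CycleFractions",
    "cycle_fractions",
    "WoundSeries",
    "wound_metrics",
    "TwoGroupTest",
    "two_group_test",
    "NCI_ACTIVITY_CUTOFF",
    "SELECTIVITY_CUTOFF",
]

#: NCI crude-extract activity criterion: active when IC50 <= 30 ug/mL.
NCI_ACTIVITY_CUTOFF = 30.0
#: Meaningful tumour selectivity: SI = CC50/IC50 strictly above 3.
SELECTIVITY_CUTOFF = 3.0


# ---------------------------------------------------------------------------
# viability and dose-response
# ---------------------------------------------------------------------------

def viability_percent(od_treated, od_control) -> float | np.ndarray:
    """Percent viability of treated wells relative to the untreated control.

    ``100 * OD_treated / OD_control``. The control OD must be positive.
    """
    od_treated = np.asarray(od_treated, dtype=float)
    od_control = np.asarray(od_control, dtype=float)
    if np.any(od_control <= 0):
        raise ValidationError("control OD must be positive")
    if np.any(od_treated < 0):
        raise ValidationError("treated OD must be non-negative")
    out = 100.0 * od_treated / od_control
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponse:
    """Replicate viabilities (%) observed across a concentration series.

    ``viability`` is an ``(n_concentrations, n_replicates)`` matrix; a 1-D
    vector is accepted and treated as a single replicate. ``true_params``
    carries generator ground truth when the data are synthetic.
    """

    concentrations: np.ndarray
    viability: np.ndarray
    cell_line: str | None = None
    true_params: dict | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if self.viability.shape[0] != self.concentrations.size:
            self.viability = self.viability.T
        if self.viability.shape[0] != self.concentrations.size:
            raise ValidationError("viability rows must match concentrations")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")

    def to_frame(self) -> pd.DataFrame:
        cols = {f"rep_{i + 1}": self.viability[:, i]
                for i in range(self.viability.shape[1])}
        return pd.DataFrame({"concentration": self.concentrations, **cols})


def _four_pl(logc: np.ndarray, top: float, bottom: float, hill: float,
             log_ic50: float) -> np.ndarray:
    # V(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill), on log10 c
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


class FourPL:
    """Four-parameter logistic dose-response model.

    V(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

    fitted by least squares on log10 concentration with multi-start
    initialization over Hill-slope magnitude and sign.
    """

    def __init__(self, concentrations, viability, cell_line: str | None = None):
        dr = (concentrations if isinstance(concentrations, DoseResponse)
              else DoseResponse(concentrations, viability, cell_line))
        if np.unique(dr.concentrations).size < 4:
            raise ValidationError("need at least 4 distinct concentrations")
        self.data = dr
        self.logc = np.log10(dr.concentrations)
        # flatten replicates
        reps = dr.viability.shape[1]
        self._x = np.repeat(self.logc, reps)
        self._y = dr.viability.ravel()

    @classmethod
    def from_dose_response(cls, dr: DoseResponse) -> "FourPL":
        return cls(dr, None, dr.cell_line)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc: str = "concentration",
                       cell_line: str | None = None) -> "FourPL":
        resp = [c for c in df.columns if c != conc]
        return cls(df[conc].to_numpy(), df[resp].to_numpy(), cell_line)

    def fit(self, bottom_bounds=(0.0, 50.0), top_bounds=(50.0, 120.0),
            hill_starts=(0.5, 1.0, 2.0, 4.0)) -> "FourPLResults":
        y = self._y
        if np.ptp(y) < 1e-9:
            raise FitError("flat response: 4PL parameters are not identifiable")
        lo_c, hi_c = self.logc.min() - 2.0, self.logc.max() + 2.0
        lower = [top_bounds[0], bottom_bounds[0], -10.0, lo_c]
        upper = [top_bounds[1], bottom_bounds[1], 10.0, hi_c]
        top0 = float(np.clip(y.max(), *top_bounds))
        bot0 = float(np.clip(y.min(), *bottom_bounds))
        mid0 = float(np.median(self.logc))

        def resid(theta):
            return _four_pl(self._x, *theta) - y

        best = None
        for h in hill_starts:
            for sign in (1.0, -1.0):
                theta0 = [top0, bot0, sign * h, mid0]
                try:
                    sol = scipy.optimize.least_squares(
                        resid, theta0, bounds=(lower, upper), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
                except Exception:  # pragma: no cover - solver edge cases
                    continue
                if not sol.success:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise FitError("4PL fit did not converge from any start")
        return FourPLResults(self, best)


class FourPLResults:
    """Fitted 4PL parameters with uncertainties and diagnostics."""

    _names = ("top", "bottom", "hill", "log10_ic50")

    def __init__(self, model: FourPL, solution):
        self.model = model
        self._theta = solution.x
        resid = solution.fun
        self.nobs = resid.size
        self.df_resid = max(self.nobs - 4, 1)
        self.ssr = float(2.0 * solution.cost)
        self.resid_sd = float(np.sqrt(self.ssr / self.df_resid))
        # covariance from the Gauss-Newton approximation J'J
        J = solution.jac
        try:
            cov = np.linalg.pinv(J.T @ J) * self.resid_sd**2
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((4, 4), np.nan)
        self.cov = cov

    # -- parameter access ---------------------------------------------------
    @property
    def top(self) -> float:
        return float(self._theta[0])

    @property
    def bottom(self) -> float:
        return float(self._theta[1])

    @property
    def hill(self) -> float:
        return float(self._theta[2])

    @property
    def ic50(self) -> float:
        return float(10.0 ** self._theta[3])

    @property
    def params(self) -> pd.Series:
        return pd.Series({"top": self.top, "bottom": self.bottom,
                          "hill": self.hill, "ic50": self.ic50})

    def bse(self) -> pd.Series:
        """Approximate standard errors (delta method for ic50)."""
        se = np.sqrt(np.diag(self.cov))
        se_ic50 = self.ic50 * np.log(10.0) * se[3]
        return pd.Series({"top": se[0], "bottom": se[1],
                          "hill": se[2], "ic50": se_ic50})

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals; the ic50 interval is built on the log
        scale and back-transformed, so it stays positive."""
        tcrit = scipy.stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        se = np.sqrt(np.diag(self.cov))
        rows = {}
        for i, name in enumerate(("top", "bottom", "hill")):
            v = self._theta[i]
            rows[name] = (v - tcrit * se[i], v + tcrit * se[i])
        l3 = self._theta[3]
        rows["ic50"] = (10.0 ** (l3 - tcrit * se[3]), 10.0 ** (l3 + tcrit * se[3]))
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    # -- derived quantities -------------------------------------------------
    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValidationError("concentrations must be positive")
        return _four_pl(np.log10(c), *self._theta)

    def icq(self, q: float) -> float:
        """Concentration producing ``q`` percent inhibition below the top
        plateau (q=50 returns the fitted ic50); solved analytically."""
        if not 0.0 < q < 100.0:
            raise ValidationError("q must lie strictly between 0 and 100")
        return float(self.ic50 * (q / (100.0 - q)) ** (1.0 / self.hill))

    def summary(self) -> str:
        name = self.model.data.cell_line or "dose-response"
        ci = self.conf_int()
        lines = [
            f"Four-parameter logistic fit: {name}",
            f"  observations: {self.nobs}   residual sd: {self.resid_sd:.4g}",
            f"  {'param':<8}{'estimate':>12}{'std err':>12}"
            f"{'[0.025':>12}{'0.975]':>12}",
        ]
        bse = self.bse()
        for p in ("top", "bottom", "hill", "ic50"):
            lines.append(
                f"  {p:<8}{self.params[p]:>12.4g}{bse[p]:>12.4g}"
                f"{ci.loc[p, 'lower']:>12.4g}{ci.loc[p, 'upper']:>12.4g}")
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 200):
        """Plot observed viabilities and the fitted curve on log-x axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dr = self.model.data
        for j in range(dr.viability.shape[1]):
            ax.plot(dr.concentrations, dr.viability[:, j], "o", color="C0",
                    alpha=0.6, label="observed" if j == 0 else None)
        grid = np.logspace(np.log10(dr.concentrations.min()),
                           np.log10(dr.concentrations.max()), n_points)
        ax.plot(grid, self.predict(grid), "-", color="C1", label="4PL fit")
        ax.axvline(self.ic50, ls="--", color="0.5", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("concentration (ug/mL)")
        ax.set_ylabel("viability (%)")
        ax.legend()
        return ax


def fit_4pl(dr: DoseResponse, **kwargs) -> FourPLResults:
    """Convenience wrapper: build a :class:`FourPL` model and fit it."""
    return FourPL.from_dose_response(dr).fit(**kwargs)


# ---------------------------------------------------------------------------
# selectivity and NCI classification
# ---------------------------------------------------------------------------

def selectivity_index(cc50: float, ic50: float,
                      ndigits: int | None = 2) -> float:
    """Selectivity index SI = CC50(normal line) / IC50(cancer line).

    Reported at two decimals by default; pass ``ndigits=None`` for full
    precision.
    """
    if cc50 <= 0 or ic50 <= 0:
        raise ValidationError("CC50 and IC50 must be positive")
    si = cc50 / ic50
    return si if ndigits is None else round_half_up(si, ndigits)


class NCIClassification(NamedTuple):
    active: bool
    selective: bool


def nci_classify(ic50: float, si: float,
                 activity_cutoff: float = NCI_ACTIVITY_CUTOFF,
                 selectivity_cutoff: float = SELECTIVITY_CUTOFF,
                 ) -> NCIClassification:
    """Classify a crude extract: active iff IC50 <= 30 ug/mL, selective iff
    SI strictly above 3."""
    return NCIClassification(active=ic50 <= activity_cutoff,
                             selective=si > selectivity_cutoff)


def cytotoxicity_profile(cc50: float,
                         ic50_by_line: Mapping[str, float]) -> pd.DataFrame:
    """Per-line SI and NCI flags given a normal-line CC50 and cancer-line
    IC50s (Table-2-style report)."""
    rows = []
    for line, ic50 in ic50_by_line.items():
        si = selectivity_index(cc50, ic50)
        active, selective = nci_classify(ic50, si)
        rows.append({"cell_line": line, "cc50": cc50, "ic50": ic50, "si": si,
                     "nci_active": active, "nci_selective": selective})
    return pd.DataFrame(rows).set_index("cell_line")


# ---------------------------------------------------------------------------
# flow cytometry: apoptosis quadrants
# ---------------------------------------------------------------------------

@dataclass
class FlowEventSet:
    """Two-channel fluorescence events on a log10 intensity scale.

    ``events`` is ``(n, 2)``: column 0 Annexin V, column 1 PI. The two gates
    split the plane into the four standard quadrants.
    """

    events: np.ndarray
    annexin_gate: float = 2.0
    pi_gate: float = 2.0
    true_weights: tuple | None = None

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2 or self.events.shape[1] != 2:
            raise ValidationError("events must be an (n, 2) array")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["annexin", "pi"])


@dataclass(frozen=True)
class QuadrantFractions:
    """Apoptosis quadrant percentages; always a partition summing to 100."""

    viable: float
    early_apoptotic: float
    late_apoptotic: float
    necrotic: float

    def __post_init__(self):
        total = (self.viable + self.early_apoptotic + self.late_apoptotic
                 + self.necrotic)
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"quadrant fractions sum to {total}, not 100")

    def as_series(self) -> pd.Series:
        return pd.Series({"viable": self.viable,
                          "early_apoptotic": self.early_apoptotic,
                          "late_apoptotic": self.late_apoptotic,
                          "necrotic": self.necrotic})


def quadrant_fractions(events: FlowEventSet | np.ndarray,
                       gates: tuple[float, float] | None = None,
                       ) -> QuadrantFractions:
    """Percent of events per Annexin/PI quadrant.

    Events exactly on a gate count as positive for that channel. Quadrants:
    viable (A-/P-), early apoptotic (A+/P-), late apoptotic (A+/P+),
    necrotic (A-/P+).
    """
    if isinstance(events, FlowEventSet):
        if gates is None:
            gates = (events.annexin_gate, events.pi_gate)
        events = events.events
    elif gates is None:
        raise ValidationError("gates are required for raw event arrays")
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValidationError("empty event set")
    gx, gy = gates
    if not (np.isfinite(gx) and np.isfinite(gy)):
        raise ValidationError("gates must be finite")
    a_pos = events[:, 0] >= gx
    p_pos = events[:, 1] >= gy
    n = events.shape[0]
    counts = np.array([
        np.sum(~a_pos & ~p_pos),  # viable
        np.sum(a_pos & ~p_pos),   # early apoptotic
        np.sum(a_pos & p_pos),    # late apoptotic
        np.sum(~a_pos & p_pos),   # necrotic
    ], dtype=float)
    pct = 100.0 * counts / n
    # exact partition: absorb float error in the largest quadrant
    pct[np.argmax(pct)] += 100.0 - pct.sum()
    return QuadrantFractions(*pct)


@dataclass(frozen=True)
class DeathSummary:
    """Total dead fraction (early + late apoptosis + necrosis) per arm and
    treated/control fold change."""

    total_treated: float
    total_control: float
    fold: float
    apoptotic_treated: float
    apoptotic_control: float
    undefined_fold: bool = False

    @property
    def fold_1dp(self) -> float:
        return round_half_up(self.fold, 1)


def death_summary(treated: QuadrantFractions,
                  control: QuadrantFractions) -> DeathSummary:
    """Summed death fractions and fold induction of total cell death."""
    tt = treated.early_apoptotic + treated.late_apoptotic + treated.necrotic
    tc = control.early_apoptotic + control.late_apoptotic + control.necrotic
    undefined = tc == 0.0
    fold = np.nan if undefined else tt / tc
    return DeathSummary(
        total_treated=tt, total_control=tc, fold=fold,
        apoptotic_treated=treated.early_apoptotic + treated.late_apoptotic,
        apoptotic_control=control.early_apoptotic + control.late_apoptotic,
        undefined_fold=undefined)


# ---------------------------------------------------------------------------
# cell cycle
# ---------------------------------------------------------------------------

@dataclass
class CellCycleHistogram:
    """Per-event DNA content with ordered phase gates.

    ``gates = (sub_g1_max, g0g1_max, s_max, g2m_max)``: events below the first
    boundary are sub-G1 (apoptotic debris), then G0/G1, S and G2/M bins;
    events above the last boundary (aggregates) are excluded.
    """

    dna_content: np.ndarray
    gates: tuple[float, float, float, float]
    true_weights: tuple | None = None

    def __post_init__(self):
        self.dna_content = np.asarray(self.dna_content, dtype=float)
        if list(self.gates) != sorted(self.gates) or len(set(self.gates)) != 4:
            raise ValidationError("gates must be strictly increasing")


@dataclass(frozen=True)
class CycleFractions:
    """Three-phase percentages over gated events (sum to 100); sub-G1 and
    aggregate fractions are reported separately as a share of all events."""

    g0g1: float
    s: float
    g2m: float
    sub_g1_pct: float = 0.0
    excluded_pct: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series({"g0g1": self.g0g1, "s": self.s, "g2m": self.g2m,
                          "sub_g1_pct": self.sub_g1_pct,
                          "excluded_pct": self.excluded_pct})


def cycle_fractions(hist: CellCycleHistogram) -> CycleFractions:
    """Threshold gating of DNA content into G0/G1, S and G2/M.

    Sub-G1 events are excluded from the three-phase normalization and
    reported separately.
    """
    x = hist.dna_content
    if x.size == 0:
        raise ValidationError("empty histogram")
    b0, b1, b2, b3 = hist.gates
    sub = np.sum(x < b0)
    g0g1 = np.sum((x >= b0) & (x < b1))
    s = np.sum((x >= b1) & (x < b2))
    g2m = np.sum((x >= b2) & (x <= b3))
    excl = np.sum(x > b3)
    n_all = x.size
    gated = g0g1 + s + g2m
    if gated == 0:
        raise ValidationError("no events inside the phase gates")
    return CycleFractions(
        g0g1=100.0 * g0g1 / gated, s=100.0 * s / gated,
        g2m=100.0 * g2m / gated,
        sub_g1_pct=100.0 * sub / n_all, excluded_pct=100.0 * excl / n_all)


# ---------------------------------------------------------------------------
# wound healing
# ---------------------------------------------------------------------------

@dataclass
class WoundSeries:
    """Wound areas over time for treated and control arms.

    The first timepoint is the baseline (freshly scratched wound).
    """

    timepoints: Sequence[float]
    treated: Sequence[float]
    control: Sequence[float]

    def __post_init__(self):
        t, a, c = map(np.asarray, (self.timepoints, self.treated, self.control))
        if not (t.size == a.size == c.size):
            raise ValidationError("timepoints and area series must align")
        if np.any(a < 0) or np.any(c < 0):
            raise ValidationError("areas must be non-negative")
        if a[0] <= 0 or c[0] <= 0:
            raise ValidationError("baseline areas must be positive")
        self.timepoints, self.treated, self.control = t, a.astype(float), c.astype(float)


def wound_metrics(series: WoundSeries) -> pd.DataFrame:
    """Percent wound closure per arm and the treated-relative-to-control
    migration metric.

    closure(t) = 100 * (A0 - A_t) / A0; ``relative_closure`` =
    100 * closure_treated / closure_control. Negative closure (wound growth)
    is allowed but flagged.
    """
    a0_t, a0_c = series.treated[0], series.control[0]
    ct = 100.0 * (a0_t - series.treated) / a0_t
    cc = 100.0 * (a0_c - series.control) / a0_c
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(cc != 0.0, 100.0 * ct / cc, np.nan)
    df = pd.DataFrame({
        "timepoint": series.timepoints,
        "closure_treated": ct,
        "closure_control": cc,
        "relative_closure": rel,
        "reduction_points": cc - ct,
        "negative_closure": (ct < 0) | (cc < 0),
    })
    return df.set_index("timepoint")


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------

class TwoGroupTest(NamedTuple):
    statistic: float
    pvalue: float
    df: float


def two_group_test(a, b) -> TwoGroupTest:
    """Unpaired two-tailed Welch t-test (Satterthwaite degrees of freedom).

    When both groups have zero variance and equal means the comparison is
    vacuous and (t=0, p=1) is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return TwoGroupTest(0.0, 1.0, float(a.size + b.size - 2))
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return TwoGroupTest(sign * np.inf, 0.0, float(a.size + b.size - 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TwoGroupTest(float(res.statistic), float(res.pvalue), float(res.df))
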