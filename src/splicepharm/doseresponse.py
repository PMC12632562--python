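"""Dose-response analysis: DMSO normalization, DSS, GR metrics, 4PL IC50,
and the group-comparison statistics used to contrast drug sensitivities.

DSS (drug sensitivity score) is the normalized area of the inhibition
curve above an activity threshold t (percent):

    DSS = 100 * A / ((100 - t) * (log10 Cmax - log10 Cmin))

with A the trapezoidal integral over log10 concentration of
max(0, inhibition - t); threshold crossings are located exactly on each
piecewise-linear segment.  Zero inhibition gives 0; complete inhibition
gives 100; higher DSS means greater sensitivity.

GR (growth-rate inhibition) rescales endpoint counts so that slow- and
fast-growing lines are comparable:

    GR(c) = 2 ** (log2(x(c)/x0) / log2(x_ctrl/x0)) - 1

GR = 1 means no effect, 0 cytostasis, < 0 cytotoxicity; GR50 is the
concentration where the fitted GR curve crosses 0.5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
                  "nM": 1e-9, "pM": 1e-12}


@dataclass
class DoseResponseCurve:
    """DMSO-normalized viability series for one (sample, drug) pair.

    Concentrations are molar and strictly ascending.  `viability` holds the
    replicate means; replicate-level points are retained for fitting.
    """

    sample_id: str
    drug: str
    concentrations: np.ndarray        # molar, ascending
    viability: np.ndarray             # replicate-averaged fraction of DMSO
    n_replicates: np.ndarray          # per concentration
    conc_rep: np.ndarray = field(default=None)  # replicate-level
    viab_rep: np.ndarray = field(default=None)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if np.any(self.viability < 0):
            raise ValueError("viability must be >= 0")
        if self.conc_rep is None:
            self.conc_rep = self.concentrations.copy()
            self.viab_rep = self.viability.copy()

    @property
    def inhibition(self) -> np.ndarray:
        """Percent inhibition; negative values indicate growth stimulation."""
        return 100.0 * (1.0 - self.viability)


@dataclass
class DSSResult:
    dss: float
    activity_threshold: float
    log10_range: tuple[float, float]


@dataclass
class GRCurve:
    concentrations: np.ndarray
    gr_values: np.ndarray
    gr50: float | None
    gr_inf: float | None
    hill: float | None
    gec50: float | None


@dataclass
class IC50Fit:
    top: float
    bottom: float
    ec50: float
    hill: float
    ic50_abs: float | None
    no_response: bool
    rss: float


def normalize_viability(raw: pd.DataFrame) -> list[DoseResponseCurve]:
    """DMSO-normalize a plate-style table into per-(sample, drug) curves.

    Expected columns: sample_id, drug, concentration, unit, replicate,
    signal, is_dmso.  Viability = signal / mean(DMSO signal) within each
    (sample, drug) context; values above 1 are permitted (growth
    stimulation).  Replicates are averaged with n recorded; replicate-level
    points are retained on the curve.
    """
    required = {"sample_id", "drug", "concentration", "replicate",
                "signal", "is_dmso"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    curves = []
    for (sid, drug), grp in raw.groupby(["sample_id", "drug"], sort=True):
        dmso = grp[grp["is_dmso"].astype(bool)]
        if dmso.empty:
            raise ValueError(f"no DMSO control wells for sample {sid}, drug {drug}")
        dmso_mean = dmso["signal"].mean()
        if dmso_mean <= 0:
            raise ValueError(
                f"DMSO mean signal is {dmso_mean} for sample {sid}, drug {drug}"
            )
        treated = grp[~grp["is_dmso"].astype(bool)].copy()
        unit = treated["unit"].iloc[0] if "unit" in treated else "M"
        scale = _UNIT_TO_MOLAR.get(str(unit))
        if scale is None:
            raise ValueError(f"unknown concentration unit {unit!r}")
        treated["conc_molar"] = treated["concentration"].astype(float) * scale
        treated["viability"] = (treated["signal"] / dmso_mean).clip(lower=0.0)
        agg = (treated.groupby("conc_molar")["viability"]
               .agg(["mean", "count"]).sort_index())
        curves.append(DoseResponseCurve(
            sample_id=sid, drug=drug,
            concentrations=agg.index.to_numpy(),
            viability=agg["mean"].to_numpy(),
            n_replicates=agg["count"].to_numpy(),
            conc_rep=treated["conc_molar"].to_numpy(),
            viab_rep=treated["viability"].to_numpy(),
        ))
    return curves


def _clipped_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    """Integral of max(0, y) over x for a piecewise-linear y(x), locating
    zero crossings exactly on each segment."""
    area = 0.0
    for i in range(len(x) - 1):
        x1, x2, y1, y2 = x[i], x[i + 1], y[i], y[i + 1]
        if y1 >= 0 and y2 >= 0:
            area += 0.5 * (y1 + y2) * (x2 - x1)
        elif y1 < 0 and y2 < 0:
            continue
        else:
            xc = x1 + (x2 - x1) * (-y1) / (y2 - y1)
            if y1 >= 0:
                area += 0.5 * y1 * (xc - x1)
            else:
                area += 0.5 * y2 * (x2 - xc)
    return area


def compute_dss(curve: DoseResponseCurve, threshold: float = 10.0) -> DSSResult:
    """Normalized thresholded area under the inhibition curve, in [0, 100]."""
    if curve.concentrations.size < 4:
        raise ValueError("DSS needs at least 4 concentrations")
    if not 0.0 <= threshold < 100.0:
        raise ValueError("activity threshold must be in [0, 100) percent")
    logc = np.log10(curve.concentrations)
    excess = curve.inhibition - threshold
    area = _clipped_trapezoid(logc, excess)
    span = logc[-1] - logc[0]
    dss = 100.0 * area / ((100.0 - threshold) * span)
    return DSSResult(dss=float(np.clip(dss, 0.0, 100.0)),
                     activity_threshold=threshold,
                     log10_range=(float(logc[0]), float(logc[-1])))


# ---------------------------------------------------------------------------
# GR metrics


def _gr_model(c, gr_inf, gec50, hill):
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** hill)


def compute_gr(x0: float, x_treated: np.ndarray, x_ctrl: float,
               concentrations: np.ndarray) -> GRCurve:
    """Growth-rate inhibition values plus a fitted GR curve and GR50.

    x0 is the initial cell count, x_treated the endpoint counts per
    concentration, x_ctrl the untreated endpoint count.  The control must
    grow (x_ctrl > x0) for the normalization to be defined.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if x_ctrl <= x0:
        raise ValueError("control did not grow (x_ctrl <= x0); GR undefined")
    x_treated = np.asarray(x_treated, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(x_treated <= 0):
        raise ValueError("treated counts must be > 0 (GR is unbounded at 0 cells)")
    denom = math.log2(x_ctrl / x0)
    gr = 2.0 ** (np.log2(x_treated / x0) / denom) - 1.0

    gr50 = gr_inf = hill = gec50 = None
    # fitting needs some response; a flat GR=1 series carries no dose signal
    if conc.size >= 4 and np.ptp(gr) > 1e-12:
        lo = np.array([-1.0, conc[0] / 100.0, 0.1])
        hi = np.array([1.0, conc[-1] * 100.0, 5.0])
        best = None
        for gec0 in (conc[0], math.sqrt(conc[0] * conc[-1]), conc[-1]):
            p0 = np.clip([min(gr.min(), 0.99), gec0, 1.0], lo, hi)
            try:
                popt, _ = optimize.curve_fit(
                    _gr_model, conc, gr, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            except RuntimeError:
                continue
            rss = float(np.sum((_gr_model(conc, *popt) - gr) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is not None:
            gr_inf, gec50, hill = (float(v) for v in best[1])
            if gr_inf < 0.5:
                r = (1.0 - gr_inf) / (0.5 - gr_inf) - 1.0
                if r > 0:
                    gr50 = float(gec50 * r ** (1.0 / hill))
    return GRCurve(concentrations=conc, gr_values=gr, gr50=gr50,
                   gr_inf=gr_inf, hill=hill, gec50=gec50)


# ---------------------------------------------------------------------------
# 4PL IC50


def _four_pl(c, top, bottom, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + (c / 10.0 ** log_ec50) ** hill)


def fit_4pl(curve: DoseResponseCurve) -> IC50Fit:
    """Bounded least-squares 4PL fit on replicate-level viability points.

    Three deterministic starts (EC50 at the low end, geometric middle and
    high end of the tested range).  A fit that does not beat a flat
    (mean-viability) model by AIC is flagged no-response with IC50
    undefined.  ic50_abs is the concentration where the fitted curve
    crosses viability 0.5, reported only when that crossing lies within
    the tested range extended by one log unit.
    """
    conc = np.asarray(curve.conc_rep, dtype=float)
    viab = np.asarray(curve.viab_rep, dtype=float)
    if np.unique(conc).size < 4:
        raise ValueError("4PL fit needs at least 4 distinct concentrations")
    lmin, lmax = math.log10(conc.min()), math.log10(conc.max())
    lo = np.array([0.5, 0.0, lmin - 2.0, 0.3])
    hi = np.array([1.5, 1.0, lmax + 2.0, 5.0])
    best = None
    for lec0 in (lmin, 0.5 * (lmin + lmax), lmax):
        p0 = np.clip(
            [min(max(viab.max(), 0.5), 1.5), min(max(viab.min(), 0.0), 1.0),
             lec0, 1.0], lo, hi)
        try:
            popt, _ = optimize.curve_fit(_four_pl, conc, viab, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((_four_pl(conc, *popt) - viab) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    n = viab.size
    rss_flat = float(np.sum((viab - viab.mean()) ** 2))
    aic_flat = n * math.log(max(rss_flat, 1e-300) / n) + 2 * 1
    if best is None:
        return IC50Fit(np.nan, np.nan, np.nan, np.nan, None, True, rss_flat)
    rss, (top, bottom, log_ec50, hillv) = best
    aic_4pl = n * math.log(max(rss, 1e-300) / n) + 2 * 4
    no_response = aic_4pl >= aic_flat
    ec50 = 10.0 ** log_ec50
    ic50_abs = None
    if not no_response and bottom < 0.5 < top:
        ratio = (top - bottom) / (0.5 - bottom) - 1.0
        if ratio > 0:
            cand = ec50 * ratio ** (1.0 / hillv)
            if 10.0 ** (lmin - 1.0) <= cand <= 10.0 ** (lmax + 1.0):
                ic50_abs = float(cand)
    return IC50Fit(top=float(top), bottom=float(bottom), ec50=float(ec50),
                   hill=float(hillv), ic50_abs=ic50_abs,
                   no_response=bool(no_response), rss=rss)


# ---------------------------------------------------------------------------
# group statistics


def mann_whitney(group_a, group_b, exact_max_n: int = 12):
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration when the combined sample size is at most
    `exact_max_n` (ties handled by midranks); otherwise the normal
    approximation with tie correction.  Returns (U, p) with U computed for
    group_a.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    if na + nb <= exact_max_n:
        mu = na * nb / 2.0
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(na + nb), na):
            u = float(ranks[list(idx)].sum() - na * (na + 1) / 2)
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def regress_vaf_dss(vaf, dss):
    """Ordinary least squares of DSS on VAF (%) with a two-sided slope test.

    Returns (slope, intercept, r, p).
    """
    vaf = np.asarray(vaf, dtype=float)
    dss = np.asarray(dss, dtype=float)
    if vaf.size != dss.size:
        raise ValueError("vaf and dss must have equal lengths")
    if vaf.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(vaf) == 0:
        raise ValueError("VAF has zero variance; slope undefined")
    if np.ptp(dss) == 0:
        # flat response: zero slope, no correlation
        return 0.0, float(dss[0]), 0.0, 1.0
    res = stats.linregress(vaf, dss)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))


def anova_tukey(groups: list, labels: list[str] | None = None,
                log_transform: bool = True):
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Applied to log10-transformed values by default, the usual scale for
    IC50 comparisons.  Returns (F, p, pairwise DataFrame with adjusted p).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
        arrays.append(np.log10(g) if log_transform else g)
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrays))]
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append((labels[i], labels[j],
                         float(hsd.statistic[i, j]), float(hsd.pvalue[i, j])))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b",
                                           "mean_diff", "p_adj"])
    return float(f_stat), float(p), pairwise
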