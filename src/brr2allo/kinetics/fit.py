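"""Exponential fitting, phase-count selection, k_app regression and
affinity-table derivation for stopped-flow nucleotide-binding traces.

Workflow, mirroring the standard pre-steady-state analysis:

1. replicate traces are normalized to their initial signal F_0 and averaged;
2. each averaged trace is fitted with F(t) = F_inf + sum_i F_i exp(-k_app,i t)
   with one or two phases; the phase count is selected by an
   extra-sum-of-squares F-test plus a 3-fold rate-separation guard;
3. apparent rates from a concentration titration are regressed linearly,
   k_app = k1 [N] + k_minus1 (slope = association rate constant, intercept =
   dissociation rate constant);
4. chase-trace decay rates give k_minus1 directly and take precedence over
   the titration intercept;
5. Kd = k_minus1 / k1 per cassette, with standard errors propagated in
   quadrature, plus named fold ratios between cassettes and nucleotides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .model import KineticTrace

__all__ = [
    "ExponentialFit",
    "PhaseSelection",
    "TitrationSeries",
    "RateRegression",
    "RateConstantSet",
    "normalize_and_average",
    "fit_exponentials",
    "select_phase_count",
    "regress_kapp",
    "assign_phases",
    "derive_affinity_table",
    "fold_ratios",
    "AmbiguousPhaseWarning",
]

log = logging.getLogger(__name__)

# deterministic optimizer settings, recorded in fit metadata
_FIT_TOL = 1e-10
_MAX_NFEV = 10_000
_K_MIN, _K_MAX = 1e-9, 1e9


class AmbiguousPhaseWarning(UserWarning):
    """Fitted rates too close to assign phases to cassettes reliably."""


@dataclass
class ExponentialFit:
    """Result of a 1- or 2-exponential fit; phases sorted fast -> slow."""

    n_phases: int
    k_app: list[float]
    amplitudes: list[float]
    f_inf: float
    k_app_se: list[float]
    amplitude_se: list[float]
    f_inf_se: float
    residual_ss: float
    n_points: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return 2 * self.n_phases + 1

    @property
    def durbin_watson(self) -> float | None:
        return self._dw

    _dw: float | None = None


@dataclass
class PhaseSelection:
    """Outcome of the 1-vs-2 phase model comparison."""

    n_phases: int
    fit1: ExponentialFit
    fit2: ExponentialFit | None
    f_statistic: float | None
    p_value: float | None
    rate_ratio: float | None
    flags: list[str] = field(default_factory=list)

    @property
    def best_fit(self) -> ExponentialFit:
        return self.fit2 if (self.n_phases == 2 and self.fit2 is not None) else self.fit1


def normalize_and_average(traces: list[KineticTrace]) -> KineticTrace:
    """Normalize each trace to its initial signal F_0 and average pointwise.

    Traces on different grids are resampled onto the first trace's grid by
    linear interpolation.  Requires at least two traces.
    """
    if len(traces) < 2:
        raise ValueError("averaging requires at least 2 traces")
    grid = traces[0].time
    stacked = []
    for tr in traces:
        f0 = tr.signal[0]
        if f0 <= 0:
            raise ValueError(f"cannot normalize: initial signal F_0 = {f0} <= 0")
        norm = tr.signal / f0
        if tr.time.shape != grid.shape or not np.allclose(tr.time, grid):
            norm = np.interp(grid, tr.time, norm)
        stacked.append(norm)
    meta = dict(traces[0].meta)
    meta["n_averaged"] = len(traces)
    meta["normalized_to_f0"] = True
    return KineticTrace(grid, np.mean(stacked, axis=0), meta)


def _seed_rate(t: np.ndarray, r: np.ndarray) -> float:
    """Initial k from a log-linear regression of |signal - F_inf| decay."""
    absr = np.abs(r)
    top = absr[0] if absr[0] > 0 else absr.max()
    mask = absr > 0.02 * top
    if mask.sum() < 3:
        return 1.0 / max(t[-1], 1e-12)
    slope, _, _, _, _ = stats.linregress(t[mask], np.log(absr[mask]))
    return max(-slope, 1.0 / (10.0 * t[-1]))


def _quantile_rate_seeds(t: np.ndarray, r: np.ndarray) -> tuple[float, float] | None:
    """Two-phase rate seeds from amplitude-decay crossing times.

    For roughly equal amplitudes, |r| crosses 60% of its initial value on
    the fast phase's watch and 10% on the slow phase's, each at
    t ~ ln(5)/k.  Returns None if the crossings cannot be located.
    """
    absr = np.abs(r)
    if absr[0] <= 0:
        return None
    g = absr / absr[0]
    ks = []
    for q in (0.6, 0.1):
        below = np.flatnonzero(g <= q)
        if below.size == 0 or t[below[0]] <= 0:
            return None
        ks.append(np.log(5.0) / t[below[0]])
    if ks[0] <= ks[1]:
        return None
    return (ks[0], ks[1])


def _sort_fast_to_slow(fit: ExponentialFit) -> None:
    order = np.argsort(fit.k_app)[::-1]
    fit.k_app = [fit.k_app[i] for i in order]
    fit.amplitudes = [fit.amplitudes[i] for i in order]
    fit.k_app_se = [fit.k_app_se[i] for i in order]
    fit.amplitude_se = [fit.amplitude_se[i] for i in order]


def fit_exponentials(trace: KineticTrace, n_phases: int) -> ExponentialFit:
    """Nonlinear least-squares fit of a 1- or 2-exponential model.

    Deterministic given the trace: initial values come from the data (F_inf
    from the last 5% of points, rate seeds from a log-linear regression;
    two-phase seeds split the single-phase rate by x10 / /10).
    Non-convergence or rates at parameter bounds are flagged, never silent.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.time, trace.signal
    if len(t) < 10:
        raise ValueError("need at least 10 points to fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")

    n_tail = max(2, len(y) // 20)
    f_inf0 = float(np.mean(y[-n_tail:]))
    r0 = y[0] - f_inf0
    span = float(np.ptp(y))
    scale = max(np.abs(y).max(), 1.0)

    flags: list[str] = []
    if span < 1e-12 * scale:
        # flat trace: no amplitude to fit
        return ExponentialFit(
            n_phases=n_phases,
            k_app=[np.nan] * n_phases,
            amplitudes=[0.0] * n_phases,
            f_inf=f_inf0,
            k_app_se=[np.nan] * n_phases,
            amplitude_se=[np.nan] * n_phases,
            f_inf_se=np.nan,
            residual_ss=float(np.sum((y - f_inf0) ** 2)),
            n_points=len(y),
            converged=False,
            flags=["non-identifiable: constant signal"],
        )

    k0 = _seed_rate(t, y - f_inf0)
    amp0 = r0 if r0 != 0 else span

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = np.full_like(t, p["f_inf"].value)
        for i in range(1, n_phases + 1):
            model += p[f"a{i}"].value * np.exp(-p[f"k{i}"].value * t)
        return model - y

    if n_phases == 1:
        seed_pairs = [(k0,)]
    else:
        # widely separated rates defeat a single log-slope estimate, so also
        # seed from the times at which the residual amplitude has decayed to
        # 60% (fast phase) and 10% (slow phase) of its initial value
        seed_pairs = [(k0 * 10.0, k0 / 10.0)]
        qseed = _quantile_rate_seeds(t, y - f_inf0)
        if qseed is not None:
            seed_pairs.insert(0, qseed)

    result = None
    for seeds in seed_pairs:
        params = lmfit.Parameters()
        params.add("f_inf", value=f_inf0)
        for i, k_seed in enumerate(seeds, start=1):
            params.add(f"k{i}", value=k_seed, min=_K_MIN, max=_K_MAX)
            params.add(f"a{i}", value=amp0 / len(seeds))
        trial = lmfit.minimize(
            residual,
            params,
            method="leastsq",
            xtol=_FIT_TOL,
            ftol=_FIT_TOL,
            max_nfev=_MAX_NFEV,
        )
        if result is None or trial.chisqr < result.chisqr:
            result = trial

    ks, amps, kse, ase = [], [], [], []
    for i in range(1, n_phases + 1):
        pk, pa = result.params[f"k{i}"], result.params[f"a{i}"]
        ks.append(float(pk.value))
        amps.append(float(pa.value))
        kse.append(float(pk.stderr) if pk.stderr is not None else np.nan)
        ase.append(float(pa.stderr) if pa.stderr is not None else np.nan)
        if pk.value <= 2 * _K_MIN or pk.value >= _K_MAX / 2:
            flags.append(f"k{i} at parameter bound")
    if not result.success:
        flags.append(f"optimizer did not converge: {result.message}")
    if result.errorbars is False:
        flags.append("standard errors unavailable (singular covariance)")

    resid = residual(result.params)
    fit = ExponentialFit(
        n_phases=n_phases,
        k_app=ks,
        amplitudes=amps,
        f_inf=float(result.params["f_inf"].value),
        k_app_se=kse,
        amplitude_se=ase,
        f_inf_se=(
            float(result.params["f_inf"].stderr)
            if result.params["f_inf"].stderr is not None
            else np.nan
        ),
        residual_ss=float(np.sum(resid**2)),
        n_points=len(y),
        converged=result.success and not flags,
        flags=flags,
    )
    fit._dw = float(np.sum(np.diff(resid) ** 2) / max(np.sum(resid**2), 1e-300))
    _sort_fast_to_slow(fit)
    return fit


def select_phase_count(
    trace: KineticTrace,
    alpha: float = 0.01,
    min_rate_ratio: float = 3.0,
) -> PhaseSelection:
    """Choose between the 1- and 2-exponential models.

    The 2-phase model is selected only if the extra-sum-of-squares F-test
    rejects the 1-phase model at ``alpha`` AND the two fitted rates are
    separated by at least ``min_rate_ratio``; both fits and the test
    statistics are retained in the result.
    """
    fit1 = fit_exponentials(trace, 1)
    flags: list[str] = []
    if "non-identifiable: constant signal" in fit1.flags:
        return PhaseSelection(1, fit1, None, None, None, None, list(fit1.flags))
    fit2 = fit_exponentials(trace, 2)
    if not fit1.converged:
        flags.append("1-phase fit flagged: " + "; ".join(fit1.flags))
    if not fit2.converged:
        flags.append("2-phase fit flagged: " + "; ".join(fit2.flags))

    n = fit1.n_points
    df1 = n - fit1.n_params
    df2 = n - fit2.n_params
    ss1, ss2 = fit1.residual_ss, fit2.residual_ss
    if ss2 <= 0 or df2 <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = max((ss1 - ss2) / (df1 - df2) / (ss2 / df2), 0.0)
        p_value = float(stats.f.sf(f_stat, df1 - df2, df2))
    ks = sorted(fit2.k_app, reverse=True)
    rate_ratio = ks[0] / ks[1] if ks[1] > 0 else np.inf
    accept2 = (
        fit2.converged
        and p_value < alpha
        and np.isfinite(rate_ratio)
        and rate_ratio >= min_rate_ratio
    )
    return PhaseSelection(
        n_phases=2 if accept2 else 1,
        fit1=fit1,
        fit2=fit2,
        f_statistic=float(f_stat),
        p_value=p_value,
        rate_ratio=float(rate_ratio),
        flags=flags,
    )


@dataclass
class TitrationSeries:
    """Apparent rates versus nucleotide concentration for one phase.

    ``points`` rows: (nucleotide_conc uM, k_app mean s^-1, k_app SD s^-1,
    n_replicates).
    """

    points: list[tuple[float, float, float, int]]
    phase_label: str = ""

    def __post_init__(self) -> None:
        concs = {p[0] for p in self.points}
        if len(concs) < 3:
            raise ValueError("need >= 3 distinct concentrations for regression")
        if any(p[2] < 0 for p in self.points):
            raise ValueError("k_app SDs must be >= 0")


@dataclass
class RateRegression:
    """Linear fit k_app = k1 [N] + k_minus1."""

    k1: float
    k1_se: float
    k_minus1: float
    k_minus1_se: float
    r_squared: float
    weighted: bool
    flags: list[str] = field(default_factory=list)


def regress_kapp(series: TitrationSeries, weighted: bool = False) -> RateRegression:
    """Least-squares regression of mean k_app on nucleotide concentration.

    Slope = k1 (uM^-1 s^-1), intercept = k_minus1 (s^-1).  With
    ``weighted=True`` points are weighted by 1/SD^2 (points with SD 0 get
    the largest finite weight present).  A negative intercept is flagged
    but retained; chase-derived dissociation rates are preferred anyway.
    """
    import statsmodels.api as sm

    conc = np.array([p[0] for p in series.points])
    kapp = np.array([p[1] for p in series.points])
    x = sm.add_constant(conc)
    if weighted:
        sd = np.array([p[2] for p in series.points])
        finite = sd[sd > 0]
        floor = finite.min() if finite.size else 1.0
        w = 1.0 / np.maximum(sd, floor) ** 2
        res = sm.WLS(kapp, x, weights=w).fit()
    else:
        res = sm.OLS(kapp, x).fit()
    intercept, slope = res.params
    ise, sse = res.bse
    flags = []
    if intercept < 0:
        flags.append("negative intercept: chase-derived k_off preferred")
    return RateRegression(
        k1=float(slope),
        k1_se=float(sse),
        k_minus1=float(intercept),
        k_minus1_se=float(ise),
        r_squared=float(res.rsquared),
        weighted=weighted,
        flags=flags,
    )


def assign_phases(
    fit: ExponentialFit,
    calibration: "RateConstantSet | None" = None,
    nucleotide: str | None = None,
    nucleotide_conc: float | None = None,
    min_ratio: float = 3.0,
) -> dict[str, int]:
    """Assign the two phases of a biphasic fit to the cassettes.

    The faster phase is labelled NC, the slower CC — nucleotide exchange at
    the catalytically active N-terminal cassette is orders of magnitude
    faster than at the C-terminal cassette.  If isolated-cassette
    calibration rates and the nucleotide concentration are supplied, the
    assignment is validated against the predicted k_app of each cassette.
    Returns a mapping cassette label -> phase index (into ``fit.k_app``).
    """
    if fit.n_phases != 2:
        raise ValueError("phase assignment requires a 2-phase fit")
    ks = fit.k_app  # already sorted fast -> slow
    if ks[1] > 0 and ks[0] / ks[1] < min_ratio:
        warnings.warn(
            f"rates {ks[0]:.3g} and {ks[1]:.3g} s^-1 are within "
            f"{min_ratio}-fold: cassette assignment ambiguous",
            AmbiguousPhaseWarning,
            stacklevel=2,
        )
    assignment = {"NC": 0, "CC": 1}
    if calibration is not None and nucleotide is not None and nucleotide_conc is not None:
        frame = calibration.to_frame()
        for cassette, idx in assignment.items():
            rows = frame[
                (frame.nucleotide == nucleotide) & (frame.cassette == cassette)
            ]
            if rows.empty:
                continue
            pred = rows.k1 * nucleotide_conc + rows.k_minus1
            lo, hi = pred.min() / min_ratio, pred.max() * min_ratio
            if not (lo <= ks[idx] <= hi):
                warnings.warn(
                    f"fitted k_app {ks[idx]:.3g} s^-1 outside calibrated "
                    f"{cassette} range [{lo:.3g}, {hi:.3g}]",
                    AmbiguousPhaseWarning,
                    stacklevel=2,
                )
    return assignment


@dataclass
class RateConstantSet:
    """Table of rate constants per (construct, nucleotide, cassette)."""

    entries: pd.DataFrame

    _COLUMNS = (
        "construct",
        "nucleotide",
        "cassette",
        "k1",
        "k1_se",
        "k_minus1",
        "k_minus1_se",
        "provenance",
    )

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "RateConstantSet":
        return cls(pd.DataFrame.from_records(records, columns=cls._COLUMNS))

    @classmethod
    def from_reference(cls, constructs: list[str] | None = None) -> "RateConstantSet":
        """Published stopped-flow rate constants as a RateConstantSet."""
        from .reference import RATE_CONSTANTS

        records = [
            {
                "construct": con,
                "nucleotide": nuc,
                "cassette": cas,
                "k1": k1,
                "k1_se": k1se,
                "k_minus1": km1,
                "k_minus1_se": km1se,
                "provenance": "published",
            }
            for (con, nuc, cas), (k1, k1se, km1, km1se) in RATE_CONSTANTS.items()
            if constructs is None or con in constructs
        ]
        return cls.from_records(records)

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def derive_affinity_table(rates: RateConstantSet) -> pd.DataFrame:
    """Kd = k_minus1 / k1 per entry, with SE propagated in quadrature.

    Entries with non-positive k1 are skipped with a log record.
    """
    rows = []
    for _, r in rates.entries.iterrows():
        if not r.k1 > 0:
            log.warning(
                "skipping %s/%s/%s: k1 = %s not positive",
                r.construct, r.nucleotide, r.cassette, r.k1,
            )
            continue
        kd = r.k_minus1 / r.k1
        rel = np.sqrt(
            ((r.k_minus1_se / r.k_minus1) ** 2 if r.k_minus1 > 0 else 0.0)
            + (r.k1_se / r.k1) ** 2
        )
        rows.append(
            {
                "construct": r.construct,
                "nucleotide": r.nucleotide,
                "cassette": r.cassette,
                "k1": r.k1,
                "k_minus1": r.k_minus1,
                "kd_uM": kd,
                "kd_se_uM": kd * rel,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows)


def fold_ratios(
    affinity: pd.DataFrame,
    isolated_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Named fold ratios from an affinity table.

    Computed ratios:

    - ``cc_vs_nc_affinity_fold``: Kd_NC / Kd_CC per nucleotide (how much
      tighter the C-terminal cassette binds);
    - ``nc_vs_cc_dissociation_fold``: k_minus1_NC / k_minus1_CC per
      nucleotide (how much faster the NC releases nucleotide);
    - ``adp_vs_atpgs_preference_fold``: Kd_ATPgS / Kd_ADP per cassette.

    Cassette-versus-cassette ratios are formed within each dual-cassette
    construct; ``isolated_pairs`` (e.g. ``[("hBrr2-NC", "hBrr2-CC")]``)
    pairs single-cassette constructs.  Missing pair members are skipped
    with a log record.
    """
    rows = []

    def _cassette_folds(scope: str, nc: pd.DataFrame, cc: pd.DataFrame, nuc: str):
        if nc.empty or cc.empty:
            log.info("fold skipped for %s/%s: missing cassette entry", scope, nuc)
            return
        a, b = nc.iloc[0], cc.iloc[0]
        rows.append(
            {"ratio": "cc_vs_nc_affinity_fold", "scope": scope, "nucleotide": nuc,
             "fold": a.kd_uM / b.kd_uM}
        )
        rows.append(
            {"ratio": "nc_vs_cc_dissociation_fold", "scope": scope, "nucleotide": nuc,
             "fold": a.k_minus1 / b.k_minus1}
        )

    for (con, nuc), grp in affinity.groupby(["construct", "nucleotide"]):
        _cassette_folds(con, grp[grp.cassette == "NC"], grp[grp.cassette == "CC"], nuc)
    for con_nc, con_cc in isolated_pairs or []:
        for nuc in affinity.nucleotide.unique():
            nc = affinity[
                (affinity.construct == con_nc)
                & (affinity.nucleotide == nuc)
                & (affinity.cassette == "NC")
            ]
            cc = affinity[
                (affinity.construct == con_cc)
                & (affinity.nucleotide == nuc)
                & (affinity.cassette == "CC")
            ]
            _cassette_folds(f"{con_nc}|{con_cc}", nc, cc, nuc)

    for (con, cas), grp in affinity.groupby(["construct", "cassette"]):
        adp = grp[grp.nucleotide == "mant-ADP"]
        atp = grp[grp.nucleotide == "mant-ATPgS"]
        if adp.empty or atp.empty:
            log.info("preference fold skipped for %s/%s", con, cas)
            continue
        rows.append(
            {"ratio": "adp_vs_atpgs_preference_fold", "scope": con,
             "nucleotide": cas, "fold": atp.iloc[0].kd_uM / adp.iloc[0].kd_uM}
        )
    return pd.DataFrame(rows)
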