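"""Hill-equation binding quantification and free-energy comparisons.

Titrations (F-EMSA fraction bound, or fluorescence polarization in mP)
are fit to the Hill equation

    response = B + A * [P]^n / (Kd^n + [P]^n)

by nonlinear least squares.  For F-EMSA fraction-bound data the baseline
B is fixed at 0 and amplitude A at 1 unless overridden; FP data fit B and
A freely in raw mP.  Replicate Kds are aggregated to mean +- sample s.d.
(Table-1-style rows), converted to standard binding free energies
``dG = -R T ln(Kd)`` (Kd in molar) and compared as ``ddG = -R T
ln(Kd_A / Kd_B)`` with first-order (delta-method) error propagation.

At 298 K a two-fold affinity change corresponds to |ddG| = RT ln 2
~ 0.41 kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 298.0

__all__ = [
    "TitrationSeries",
    "HillModel",
    "HillResults",
    "AffinityEstimate",
    "FreeEnergyDelta",
    "normalize_fraction_bound",
    "fit_hill",
    "aggregate_replicates",
    "delta_g",
    "delta_delta_g",
    "dilution_series",
]


def dilution_series(top_nM: float = 2000.0, points: int = 12,
                    factor: float = 2.0) -> np.ndarray:
    """Protein concentration grid: ``points``-step serial dilution from
    ``top_nM`` downward (ascending order), e.g. ~1 nM .. 2 uM."""
    return top_nM / factor ** np.arange(points)[::-1]


def normalize_fraction_bound(bound_intensity: float, free_intensity: float
                             ) -> float:
    """Fraction bound from band intensities: bound / (bound + free)."""
    if bound_intensity < 0 or free_intensity < 0:
        raise ValueError("intensities must be non-negative")
    total = bound_intensity + free_intensity
    if total == 0:
        raise ValueError("bound + free intensity must be positive")
    return bound_intensity / total


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: protein concentrations (nM) vs binding response."""

    concentrations_nM: np.ndarray
    responses: np.ndarray
    assay: str = "femsa"  # "femsa" (fraction bound) or "fp" (mP)
    rna: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_nM, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations_nM", conc)
        object.__setattr__(self, "responses", resp)
        if conc.size != resp.size:
            raise ValueError("concentration and response lengths differ")
        if conc.size < 5:
            raise ValueError("need >= 5 titration points")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        if self.assay not in ("femsa", "fp"):
            raise ValueError(f"unknown assay {self.assay!r}")


def hill_response(conc: np.ndarray, kd: float, n: float,
                  amplitude: float = 1.0, baseline: float = 0.0) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            conc > 0, conc ** n / (kd ** n + conc ** n), 0.0
        )
    return baseline + amplitude * frac


@dataclass(frozen=True)
class HillResults:
    """Converged Hill-fit parameters with covariance-derived errors."""

    kd_nM: float
    hill_n: float
    amplitude: float
    baseline: float
    kd_se: float
    hill_n_se: float
    amplitude_se: float
    baseline_se: float
    converged: bool
    rss: float
    series: TitrationSeries
    censored_hint: str | None = None  # e.g. ">2000" when Kd exceeds the grid

    @property
    def params(self) -> dict[str, float]:
        return {"kd_nM": self.kd_nM, "hill_n": self.hill_n,
                "amplitude": self.amplitude, "baseline": self.baseline}

    def predict(self, conc: np.ndarray | None = None) -> np.ndarray:
        if conc is None:
            conc = self.series.concentrations_nM
        return hill_response(conc, self.kd_nM, self.hill_n,
                             self.amplitude, self.baseline)

    def plot(self, ax=None):
        """Titration points and the fitted Hill curve (log-x, matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        conc = self.series.concentrations_nM
        ax.semilogx(conc, self.series.responses, "o", label="data")
        grid = np.geomspace(conc[conc > 0].min(), conc.max(), 200)
        ax.semilogx(grid, self.predict(grid), "-",
                    label=f"fit, Kd={self.kd_nM:.3g} nM")
        ax.set_xlabel("[protein] (nM)")
        ax.set_ylabel("fraction bound" if self.series.assay == "femsa"
                      else "polarization (mP)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"Hill fit ({self.series.assay.upper()}"
            + (f", {self.series.protein} x {self.series.rna}"
               if self.series.protein or self.series.rna else "") + ")",
            f"  Kd        = {self.kd_nM:.4g} +- {self.kd_se:.2g} nM"
            + (f"  [suggest censored {self.censored_hint}]"
               if self.censored_hint else ""),
            f"  Hill n    = {self.hill_n:.3g} +- {self.hill_n_se:.2g}",
            f"  amplitude = {self.amplitude:.3g} +- {self.amplitude_se:.2g}",
            f"  baseline  = {self.baseline:.3g} +- {self.baseline_se:.2g}",
            f"  RSS = {self.rss:.4g}, converged = {self.converged}",
        ]
        return "\n".join(lines)


class HillModel:
    """Hill-equation binding model for one titration, statsmodels style.

    >>> model = HillModel(series)          # doctest: +SKIP
    >>> res = model.fit(fix_n=True)        # doctest: +SKIP
    >>> res.kd_nM, res.kd_se               # doctest: +SKIP
    """

    def __init__(self, series: TitrationSeries,
                 fix_baseline: float | None = None,
                 fix_amplitude: float | None = None):
        self.series = series
        # F-EMSA fraction-bound curves are anchored at 0..1 by default
        if series.assay == "femsa":
            self.fix_baseline = 0.0 if fix_baseline is None else fix_baseline
            self.fix_amplitude = 1.0 if fix_amplitude is None else fix_amplitude
        else:
            self.fix_baseline = fix_baseline
            self.fix_amplitude = fix_amplitude

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, assay: str = "femsa",
                       rna: str = "", protein: str = "", **kwargs
                       ) -> "HillModel":
        """Build from a table with columns ``concentration_nM`` and
        ``response`` (or ``bound_intensity``/``free_intensity``)."""
        if "response" in frame.columns:
            resp = frame["response"].to_numpy(dtype=float)
        elif {"bound_intensity", "free_intensity"} <= set(frame.columns):
            resp = np.array([
                normalize_fraction_bound(b, f)
                for b, f in zip(frame["bound_intensity"],
                                frame["free_intensity"])
            ])
        else:
            raise ValueError(
                "need a 'response' column or bound/free intensity columns"
            )
        series = TitrationSeries(
            concentrations_nM=frame["concentration_nM"].to_numpy(dtype=float),
            responses=resp, assay=assay, rna=rna, protein=protein,
        )
        return cls(series, **kwargs)

    def fit(self, init: dict[str, float] | None = None,
            fix_n: bool = False) -> HillResults:
        series = self.series
        conc, resp = series.concentrations_nM, series.responses
        init = init or {}

        free_names = ["kd_nM"]
        if not fix_n:
            free_names.append("hill_n")
        if self.fix_amplitude is None:
            free_names.append("amplitude")
        if self.fix_baseline is None:
            free_names.append("baseline")

        span = resp.max() - resp.min()
        # half-saturation concentration as Kd guess
        half = resp.min() + 0.5 * span
        kd0 = init.get("kd_nM", float(np.interp(half, resp, conc))
                       if span > 0 else float(np.median(conc[conc > 0])))
        kd0 = max(kd0, float(conc[conc > 0].min()) * 0.1)
        defaults = {
            "kd_nM": kd0,
            "hill_n": init.get("hill_n", 1.0),
            "amplitude": init.get("amplitude", span if span > 0 else 1.0),
            "baseline": init.get("baseline", float(resp.min())),
        }
        lower = {"kd_nM": 1e-6, "hill_n": 1e-2, "amplitude": -np.inf,
                 "baseline": -np.inf}
        upper = {"kd_nM": np.inf, "hill_n": 10.0, "amplitude": np.inf,
                 "baseline": np.inf}

        def model_fn(x, *theta):
            values = dict(zip(free_names, theta))
            kd = values["kd_nM"]
            n = values.get("hill_n", 1.0 if fix_n else defaults["hill_n"])
            if fix_n:
                n = 1.0
            amp = values.get(
                "amplitude",
                self.fix_amplitude if self.fix_amplitude is not None else 1.0,
            )
            base = values.get(
                "baseline",
                self.fix_baseline if self.fix_baseline is not None else 0.0,
            )
            return hill_response(x, kd, n, amp, base)

        p0 = [defaults[name] for name in free_names]
        bounds = ([lower[name] for name in free_names],
                  [upper[name] for name in free_names])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model_fn, conc, resp, p0=p0,
                                       bounds=bounds, maxfev=20_000)
            converged = bool(np.all(np.isfinite(popt)))
        except RuntimeError:
            popt = np.array(p0)
            pcov = np.full((len(p0), len(p0)), np.nan)
            converged = False

        values = dict(zip(free_names, popt))
        ses = dict(zip(free_names, np.sqrt(np.abs(np.diag(pcov)))))
        kd = float(values["kd_nM"])
        n = 1.0 if fix_n else float(values.get("hill_n", 1.0))
        amp = float(values.get(
            "amplitude",
            self.fix_amplitude if self.fix_amplitude is not None else 1.0))
        base = float(values.get(
            "baseline",
            self.fix_baseline if self.fix_baseline is not None else 0.0))
        resid = resp - hill_response(conc, kd, n, amp, base)
        censored = None
        if converged and kd >= conc.max():
            censored = f">{conc.max():g}"
        return HillResults(
            kd_nM=kd, hill_n=n, amplitude=amp, baseline=base,
            kd_se=float(ses.get("kd_nM", np.nan)),
            hill_n_se=0.0 if fix_n else float(ses.get("hill_n", np.nan)),
            amplitude_se=float(ses.get("amplitude", 0.0)),
            baseline_se=float(ses.get("baseline", 0.0)),
            converged=converged, rss=float(np.sum(resid ** 2)),
            series=series, censored_hint=censored,
        )


def fit_hill(series: TitrationSeries, init: dict[str, float] | None = None,
             fix_n: bool = False, **model_kwargs) -> HillResults:
    """Convenience wrapper: ``HillModel(series, **kw).fit(init, fix_n)``."""
    return HillModel(series, **model_kwargs).fit(init=init, fix_n=fix_n)


@dataclass(frozen=True)
class AffinityEstimate:
    """Replicate-aggregated Kd (one Table-1-style row).

    A censored estimate (``censored=True``) carries ``bound_nM`` (a lower
    bound such as ">2000") instead of a usable mean.
    """

    kd_nM: float
    sd_nM: float
    n: int
    assay: str = "femsa"
    protein: str = ""
    rna: str = ""
    censored: bool = False
    bound_nM: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")
        if not self.censored and (self.kd_nM <= 0 or self.sd_nM < 0):
            raise ValueError("need Kd > 0 and s.d. >= 0")

    def __str__(self) -> str:
        if self.censored:
            return f"Kd > {self.bound_nM:g} nM (censored, n={self.n})"
        return f"Kd = {self.kd_nM:g} +- {self.sd_nM:g} nM (n={self.n})"


def aggregate_replicates(fits: list[HillResults | AffinityEstimate],
                         assay: str | None = None) -> AffinityEstimate:
    """Mean +- sample s.d. of replicate Kds.

    A single replicate reports the fit's own standard error as its
    uncertainty.  Censored inputs collapse to the smallest lower bound.
    """
    if len(fits) == 0:
        raise ValueError("no fits to aggregate")
    censored_bounds = []
    kds, ses = [], []
    protein = rna = ""
    for fit in fits:
        if isinstance(fit, AffinityEstimate):
            if fit.censored:
                censored_bounds.append(fit.bound_nM)
            else:
                kds.append(fit.kd_nM)
                ses.append(fit.sd_nM)
            protein, rna = fit.protein, fit.rna
            assay = assay or fit.assay
        else:
            if not fit.converged:
                continue
            if fit.censored_hint is not None:
                censored_bounds.append(float(fit.censored_hint.lstrip(">")))
            else:
                kds.append(fit.kd_nM)
                ses.append(fit.kd_se)
            protein, rna = fit.series.protein, fit.series.rna
            assay = assay or fit.series.assay
    assay = assay or "femsa"
    if censored_bounds and not kds:
        bound = min(censored_bounds)
        return AffinityEstimate(kd_nM=bound, sd_nM=0.0, n=len(censored_bounds),
                                assay=assay, protein=protein, rna=rna,
                                censored=True, bound_nM=bound)
    if not kds:
        raise ValueError("no converged, uncensored fits to aggregate")
    if len(kds) == 1:
        return AffinityEstimate(kd_nM=kds[0], sd_nM=ses[0], n=1, assay=assay,
                                protein=protein, rna=rna)
    return AffinityEstimate(
        kd_nM=float(np.mean(kds)), sd_nM=float(np.std(kds, ddof=1)),
        n=len(kds), assay=assay, protein=protein, rna=rna,
    )


@dataclass(frozen=True)
class FreeEnergyDelta:
    """dG or ddG in kcal/mol with first-order propagated uncertainty."""

    value_kcal_mol: float
    sd_kcal_mol: float
    temperature_K: float
    kind: str  # "dG" or "ddG"
    estimate_a: AffinityEstimate | None = None
    estimate_b: AffinityEstimate | None = None

    def __str__(self) -> str:
        return (f"{self.kind} = {self.value_kcal_mol:+.3f} "
                f"+- {self.sd_kcal_mol:.3f} kcal/mol @ {self.temperature_K:g} K")


def delta_g(est: AffinityEstimate,
            temperature_K: float = DEFAULT_TEMPERATURE_K) -> FreeEnergyDelta:
    """Standard binding free energy dG = -R T ln(Kd), Kd converted nM -> M.

    Uncertainty by the delta method: sigma_dG = R T sigma_Kd / Kd.
    """
    if est.censored:
        raise ValueError(
            f"censored estimate ({est}) has no point dG; only a bound"
        )
    kd_molar = est.kd_nM * 1e-9
    value = -R_KCAL * temperature_K * np.log(kd_molar)
    sd = R_KCAL * temperature_K * est.sd_nM / est.kd_nM
    return FreeEnergyDelta(value_kcal_mol=float(value), sd_kcal_mol=float(sd),
                           temperature_K=temperature_K, kind="dG",
                           estimate_a=est)


def delta_delta_g(est_a: AffinityEstimate, est_b: AffinityEstimate,
                  temperature_K: float = DEFAULT_TEMPERATURE_K
                  ) -> FreeEnergyDelta:
    """ddG = dG(A) - dG(B) = -R T ln(Kd_A / Kd_B), errors in quadrature.

    The nM -> M unit conversion cancels in the ratio.  Negative ddG means
    A binds less tightly than B relative to their shared reference.
    """
    if est_a.censored or est_b.censored:
        raise ValueError("ddG undefined for censored estimates; "
                         "only a directional bound is available")
    value = -R_KCAL * temperature_K * np.log(est_a.kd_nM / est_b.kd_nM)
    sd = np.hypot(R_KCAL * temperature_K * est_a.sd_nM / est_a.kd_nM,
                  R_KCAL * temperature_K * est_b.sd_nM / est_b.kd_nM)
    return FreeEnergyDelta(value_kcal_mol=float(value), sd_kcal_mol=float(sd),
                           temperature_K=temperature_K, kind="ddG",
                           estimate_a=est_a, estimate_b=est_b)
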