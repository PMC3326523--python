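"""Isothermal titration calorimetry: isotherm simulation, fitting, and
thermodynamic interpretation.

Model
-----
A macromolecule M sits in a perfusion cell of volume ``V0`` at total
concentration ``Mt`` and is titrated with injectant X.  For a single set of
``N`` identical, independent sites the concentration ``C`` of bound
injectant satisfies the mass-balance quadratic

    K_a = C / ((N·Mt - C)(Xt - C)),

whose physical root is evaluated in a numerically stable form.  The
cumulative heat content of the cell after injection *i* is
``Q_i = ΔH · C_i · V0`` and the measured heat of injection *i* is

    q_i = Q_i - Q_{i-1} + (dV_i / V0) · (Q_i + Q_{i-1}) / 2,

the last term being the standard displaced-volume correction for an
overflow cell.  Total concentrations after cumulative injected volume ΔV
follow the instrument bookkeeping

    Mt = M0 · (1 - ΔV/2V0) / (1 + ΔV/2V0),
    Xt = X0 · (ΔV/V0) / (1 + ΔV/2V0).

Thermodynamics: ΔG = -R·T·ln K_a and ΔS = (ΔH - ΔG)/T with R in
cal/(mol·K); all heats are handled in μcal, enthalpies in cal/mol.

Multivalent peptides
--------------------
A peptide carrying *m* equivalent, independent reader-binding acetyl-lysine
sites titrated into the reader is simulated with total site concentration
``m·Xt``; fitting such data with the single-set-of-sites model (protein in
the cell) returns an apparent stoichiometry N = 1/m — the classic N ≈ 0.5
signature of two reader domains engaging one diacetylated peptide.  A
bidentate peptide (both acetyl-lysines in one pocket) is instead a single
binding event with N ≈ 1 and boosted affinity; ``ITCFitResults.verdict``
distinguishes the two from the fitted N and its confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

#: gas constant, cal/(mol K)
R_CAL = 1.987204258640832

CAL_TO_UCAL = 1e6

Orientation = Literal["protein_in_cell", "peptide_in_cell"]


class NoBindingError(RuntimeError):
    """Raised when the heats carry no detectable binding signal."""


class FitError(RuntimeError):
    """Raised on optimizer failure; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def default_injection_schedule(
    first_volume: float = 2e-6, volume: float = 8e-6, n: int = 29
) -> list[float]:
    """The standard VP-ITC schedule: a small first injection followed by
    ``n`` identical injections (volumes in liters)."""
    return [first_volume] + [volume] * n


@dataclass
class TitrationExperiment:
    """An ITC design plus (optionally) its measured per-injection heats."""

    cell_conc: float  # molar, species in the cell
    syringe_conc: float  # molar
    cell_volume: float = 1.4e-3  # liters
    injection_volumes: Sequence[float] = field(
        default_factory=default_injection_schedule
    )
    temperature: float = 288.15  # kelvin
    heats: Sequence[float] | None = None  # μcal per injection
    dilution_heats: Sequence[float] | float | None = None  # μcal per injection
    cell_species: str = "protein"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")
        if not 273.0 <= self.temperature <= 333.0:
            raise ValueError("temperature outside the supported range [273, 333] K")
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise ValueError("one heat per injection required")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def total_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """(Mt, Xt) after each injection under overflow-cell bookkeeping."""
        dv = np.cumsum(np.asarray(self.injection_volumes, dtype=float))
        v0 = self.cell_volume
        mt = self.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = self.syringe_conc * (dv / v0) / (1 + dv / (2 * v0))
        return mt, xt

    def corrected_heats(self) -> np.ndarray:
        """Measured heats minus dilution heats (μcal)."""
        if self.heats is None:
            raise ValueError("experiment carries no measured heats")
        q = np.asarray(self.heats, dtype=float)
        if self.dilution_heats is None:
            return q
        d = np.asarray(self.dilution_heats, dtype=float)
        if d.ndim == 0:
            d = np.full_like(q, float(d))
        return q - d


@dataclass
class BindingParameters:
    """Fitted or ground-truth single-class binding parameters.

    ``n_sites`` is moles of injectant bound per mole of cell species at
    saturation; ``k_a`` in 1/M; ``dh`` in cal/mol of injectant.
    """

    n_sites: float
    k_a: float
    dh: float
    temperature: float = 288.15
    n_sites_err: float = float("nan")
    k_a_err: float = float("nan")
    dh_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_a <= 0:
            raise ValueError("K_a must be positive")
        if self.n_sites <= 0:
            raise ValueError("N must be positive")

    @property
    def k_d(self) -> float:
        return 1.0 / self.k_a

    @property
    def dg(self) -> float:
        return thermodynamics(self.k_a, self.dh, self.temperature)[0]

    @property
    def ds(self) -> float:
        return thermodynamics(self.k_a, self.dh, self.temperature)[1]


def bound_site_concentration(
    site_conc: float | np.ndarray, ligand_conc: float | np.ndarray, k_a: float
) -> np.ndarray:
    """Physical root of K_a = C/((A-C)(B-C)) for complex concentration C.

    Evaluated in the subtraction-free form C = 2AB / (S + sqrt(S² - 4AB))
    with S = A + B + 1/K_a, which stays accurate for both very tight and
    very weak binding (K_a → 0 degenerates smoothly to the linear regime
    C ≈ K_a·A·B).
    """
    a = np.asarray(site_conc, dtype=float)
    b = np.asarray(ligand_conc, dtype=float)
    s = a + b + 1.0 / k_a
    disc = np.sqrt(np.square(s) - 4.0 * a * b)
    return np.where(a * b > 0, 2.0 * a * b / (s + disc), 0.0)


def cumulative_heats(
    params: BindingParameters,
    experiment: TitrationExperiment,
    injectant_sites: int = 1,
) -> np.ndarray:
    """Cell heat content (μcal) after each injection.

    ``injectant_sites`` > 1 models a peptide injectant carrying that many
    equivalent, independent, non-interacting protein-binding sites; the
    enthalpy is then per mole of *site* binding events.
    """
    mt, xt = experiment.total_concentrations()
    site_a = params.n_sites * mt
    site_b = injectant_sites * xt
    c = bound_site_concentration(site_a, site_b, params.k_a)
    return params.dh * c * experiment.cell_volume * CAL_TO_UCAL


def simulate_isotherm(
    params: BindingParameters,
    experiment: TitrationExperiment,
    injectant_sites: int = 1,
) -> np.ndarray:
    """Per-injection heats (μcal) with the displaced-volume correction."""
    q = cumulative_heats(params, experiment, injectant_sites)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dv = np.asarray(experiment.injection_volumes, dtype=float)
    return q - q_prev + (dv / experiment.cell_volume) * (q + q_prev) / 2.0


def c_value(params: BindingParameters, experiment: TitrationExperiment) -> float:
    """Wiseman c parameter N·K_a·[cell species]; governs curvature."""
    return params.n_sites * params.k_a * experiment.cell_conc


def thermodynamics(k_a: float, dh: float, temperature: float) -> tuple[float, float]:
    """(ΔG, ΔS) in cal/mol and cal/(mol·K) from ΔG = -RT ln K_a and
    ΔS = (ΔH - ΔG)/T."""
    if k_a <= 0 or temperature <= 0:
        raise ValueError("K_a and T must be positive")
    dg = -R_CAL * temperature * math.log(k_a)
    ds = (dh - dg) / temperature
    return dg, ds


def fold_change(k_d_ref: float, k_d_new: float) -> float:
    """Affinity gain of the new interaction over the reference (>1 means
    tighter)."""
    if k_d_ref <= 0 or k_d_new <= 0:
        raise ValueError("dissociation constants must be positive")
    return k_d_ref / k_d_new


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


def _weights(experiment: TitrationExperiment, exclude_first: bool) -> np.ndarray:
    """First-injection down-weighting: the small priming injection suffers
    from syringe backlash and is conventionally discounted."""
    w = np.ones(experiment.n_injections)
    volumes = np.asarray(experiment.injection_volumes)
    if experiment.n_injections > 1 and volumes[0] < volumes[1]:
        w[0] = 0.0 if exclude_first else 0.1
    return w


def _noise_floor(heats: np.ndarray) -> float:
    """Robust per-injection noise estimate from successive differences."""
    if len(heats) < 3:
        return 0.0
    return float(np.median(np.abs(np.diff(heats)))) / math.sqrt(2) * 1.4826


class SingleSiteModel:
    """Single-set-of-identical-sites binding model for one titration.

    Mirrors the statsmodels idiom: build the model from data, call
    :meth:`fit`, and read estimates off the returned results object.

    Parameters
    ----------
    experiment:
        A :class:`TitrationExperiment` with measured heats.  Dilution heats
        attached to the experiment are subtracted before fitting; when none
        are supplied a constant offset is co-fitted instead.
    exclude_first:
        Drop (rather than down-weight) the small first injection.
    """

    n_params = 3

    def __init__(
        self, experiment: TitrationExperiment, exclude_first: bool = False
    ) -> None:
        if experiment.heats is None:
            raise ValueError("experiment carries no measured heats to fit")
        self.experiment = experiment
        self.exclude_first = exclude_first
        self.heats = experiment.corrected_heats()
        self.fit_offset = experiment.dilution_heats is None
        informative = int(np.sum(_weights(experiment, exclude_first) > 0))
        if informative < 8:
            raise ValueError("at least 8 informative injections required")

    # -- internals ----------------------------------------------------------
    def _predict(self, theta: np.ndarray) -> np.ndarray:
        n, log10_ka, dh = theta[:3]
        params = BindingParameters(
            n, 10.0**log10_ka, dh, self.experiment.temperature
        )
        model = simulate_isotherm(params, self.experiment)
        if self.fit_offset:
            model = model + theta[3]
        return model

    def _residuals(self, theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
        return weights * (self._predict(theta) - self.heats)

    def _initializations(self) -> list[np.ndarray]:
        exp = self.experiment
        mt, xt = exp.total_concentrations()
        dv = np.asarray(exp.injection_volumes)
        heats = self.heats
        # enthalpy guess from the largest early injection, assuming complete
        # binding of the injected material
        idx = 1 if exp.n_injections > 1 else 0
        moles = exp.syringe_conc * dv[idx]
        dh0 = heats[idx] / CAL_TO_UCAL / moles if moles > 0 else -1e4
        if abs(dh0) < 10.0:
            dh0 = math.copysign(1e3, dh0 if dh0 != 0 else -1.0)
        # N guess from the molar ratio at the half-height of the cumulative
        # heat (the inflection of a sigmoid isotherm)
        cum = np.abs(np.cumsum(heats))
        ratio = xt / mt
        half = cum[-1] / 2.0
        n0 = float(np.clip(np.interp(half, cum, ratio), 0.1, 5.0))
        inits = []
        for log10_ka in (4.0, 5.0, 6.0):
            theta = [n0, log10_ka, dh0]
            if self.fit_offset:
                theta.append(0.0)
            inits.append(np.array(theta))
        return inits

    def fit(self) -> "ITCFitResults":
        """Weighted least squares over (N, K_a, ΔH) with three deterministic
        multi-starts; raises :class:`NoBindingError` for flat data."""
        heats = self.heats
        span = float(np.max(heats) - np.min(heats))
        noise = _noise_floor(heats)
        if span <= max(3.0 * noise, 1e-9):
            raise NoBindingError(
                "no binding detected: heat span is within the noise floor"
            )
        weights = _weights(self.experiment, self.exclude_first)
        lower = [1e-2, 0.0, -1e7]
        upper = [20.0, 12.0, 1e7]
        if self.fit_offset:
            lower.append(-1e5)
            upper.append(1e5)
        best = None
        last = None
        for theta0 in self._initializations():
            try:
                sol = least_squares(
                    self._residuals,
                    np.clip(theta0, lower, upper),
                    args=(weights,),
                    bounds=(lower, upper),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            last = sol
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("single-site fit did not converge", last)
        return ITCFitResults(self, best, weights)

    # functional spellings used throughout the pipeline
    @classmethod
    def from_trace(cls, experiment: TitrationExperiment, **kw) -> "SingleSiteModel":
        return cls(experiment, **kw)


def _covariance(sol, n_obs: int, n_par: int) -> np.ndarray:
    """Parameter covariance from the local quadratic approximation
    (Gauss-Newton J'J) scaled by the residual variance."""
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
    return cov


Verdict = Literal[
    "one_to_one", "two_domains_per_peptide", "bidentate_single_event", "indeterminate"
]


def interpret_stoichiometry(
    n: float,
    n_err: float,
    orientation: Orientation = "protein_in_cell",
    z: float = 2.0,
    affinity_gain: float | None = None,
) -> Verdict:
    """Read the multivalency story off a fitted site number.

    With the reader protein in the cell, N within its confidence interval
    of 0.5 indicates two reader molecules per (diacetylated) peptide; N
    near 1 is either a plain 1:1 interaction or a bidentate single binding
    event — the two are only distinguished by a large affinity gain over
    the monoacetylated reference, so ``bidentate_single_event`` is returned
    only when such a gain (≥ 5-fold) is supplied.  Anything unresolved is
    ``indeterminate``.
    """
    if not math.isfinite(n_err):
        n_err = 0.0
    half = z * n_err
    covers_half = abs(n - 0.5) <= max(half, 0.05)
    covers_one = abs(n - 1.0) <= max(half, 0.1)
    if orientation == "protein_in_cell" and covers_half and not covers_one:
        return "two_domains_per_peptide"
    if covers_one and not (orientation == "protein_in_cell" and covers_half):
        if affinity_gain is not None and affinity_gain >= 5.0:
            return "bidentate_single_event"
        return "one_to_one"
    return "indeterminate"


class ITCFitResults:
    """Results of a single-set-of-sites fit.

    Attributes
    ----------
    params : BindingParameters
        Point estimates with standard errors; derived ΔG/ΔS/K_D hang off
        the params object.
    """

    def __init__(self, model: SingleSiteModel, sol, weights: np.ndarray) -> None:
        self.model = model
        self._sol = sol
        n, log10_ka, dh = sol.x[:3]
        self.offset = float(sol.x[3]) if model.fit_offset else 0.0
        n_obs = int(np.sum(weights > 0))
        cov = _covariance(sol, n_obs, len(sol.x))
        ka = 10.0**log10_ka
        ka_err = abs(ka * math.log(10.0)) * math.sqrt(abs(cov[1, 1]))
        self.params = BindingParameters(
            n_sites=float(n),
            k_a=float(ka),
            dh=float(dh),
            temperature=model.experiment.temperature,
            n_sites_err=math.sqrt(abs(cov[0, 0])),
            k_a_err=ka_err,
            dh_err=math.sqrt(abs(cov[2, 2])),
        )
        self.ssr = float(2.0 * sol.cost)
        self.n_obs = n_obs
        self.c_value = c_value(self.params, model.experiment)
        if not 1e-2 <= self.c_value <= 1e4:
            warnings.warn(
                f"c-value {self.c_value:.3g} outside [0.01, 1e4]; parameters "
                "may be poorly determined",
                stacklevel=2,
            )

    @property
    def aicc(self) -> float:
        k = len(self._sol.x)
        n = self.n_obs
        aic = n * math.log(max(self.ssr / n, 1e-300)) + 2 * k
        if n - k - 1 > 0:
            aic += 2 * k * (k + 1) / (n - k - 1)
        return aic

    def fitted_heats(self) -> np.ndarray:
        return self.model._predict(self._sol.x)

    def verdict(
        self,
        orientation: Orientation = "protein_in_cell",
        affinity_gain: float | None = None,
    ) -> Verdict:
        return interpret_stoichiometry(
            self.params.n_sites,
            self.params.n_sites_err,
            orientation,
            affinity_gain=affinity_gain,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Single-set-of-sites ITC fit",
            "===========================",
            f"injections used     : {self.n_obs}",
            f"temperature (K)     : {self.model.experiment.temperature:.2f}",
            f"N  (sites)          : {p.n_sites:.4f} +/- {p.n_sites_err:.4f}",
            f"K_a (1/M)           : {p.k_a:.4e} +/- {p.k_a_err:.2e}",
            f"K_D (M)             : {p.k_d:.4e}",
            f"dH (cal/mol)        : {p.dh:.1f} +/- {p.dh_err:.1f}",
            f"dG (cal/mol)        : {p.dg:.1f}",
            f"dS (cal/mol/K)      : {p.ds:.3f}",
            f"c-value             : {self.c_value:.3g}",
            f"SSR (ucal^2)        : {self.ssr:.4g}",
        ]
        if self.model.fit_offset:
            lines.append(f"fitted offset (ucal): {self.offset:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "model": "single_site",
            "N": p.n_sites,
            "N_err": p.n_sites_err,
            "Ka_per_M": p.k_a,
            "Ka_err": p.k_a_err,
            "Kd_M": p.k_d,
            "dH_cal_per_mol": p.dh,
            "dH_err": p.dh_err,
            "dG_cal_per_mol": p.dg,
            "dS_cal_per_mol_K": p.ds,
            "temperature_K": self.model.experiment.temperature,
            "c_value": self.c_value,
            "ssr": self.ssr,
            "aicc": self.aicc,
        }

    def plot(self, ax=None):
        """Molar-ratio vs normalized heat plot with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        exp = self.model.experiment
        mt, xt = exp.total_concentrations()
        dv = np.asarray(exp.injection_volumes)
        per_mol = 1e-6 / (exp.syringe_conc * dv)  # ucal -> cal/mol injectant
        ax.plot(xt / mt, self.model.heats * per_mol / 1e3, "o", label="data")
        ax.plot(xt / mt, self.fitted_heats() * per_mol / 1e3, "-", label="fit")
        ax.set_xlabel("molar ratio (injectant / cell species)")
        ax.set_ylabel("kcal per mol of injectant")
        ax.legend()
        return ax


class TwoSiteModel:
    """Two independent classes of sites on the cell species.

    The free-injectant concentration is solved numerically per injection;
    use :meth:`fit` and compare ``results.aicc`` with the single-site fit.
    """

    n_params = 6

    def __init__(
        self, experiment: TitrationExperiment, exclude_first: bool = False
    ) -> None:
        if experiment.heats is None:
            raise ValueError("experiment carries no measured heats to fit")
        self.experiment = experiment
        self.exclude_first = exclude_first
        self.heats = experiment.corrected_heats()
        informative = int(np.sum(_weights(experiment, exclude_first) > 0))
        if informative < 10:
            raise ValueError(
                "two-site fit under-determined: fewer than 10 informative "
                "injections; use the single-site model"
            )

    @staticmethod
    def _cumulative(theta: np.ndarray, experiment: TitrationExperiment) -> np.ndarray:
        n1, lk1, h1, n2, lk2, h2 = theta
        k1, k2 = 10.0**lk1, 10.0**lk2
        mt, xt = experiment.total_concentrations()
        q = np.empty_like(xt)
        from scipy.optimize import brentq

        for i, (m, x) in enumerate(zip(mt, xt)):
            if x == 0:
                q[i] = 0.0
                continue

            def balance(xf, m=m, x=x):
                b1 = n1 * m * k1 * xf / (1 + k1 * xf)
                b2 = n2 * m * k2 * xf / (1 + k2 * xf)
                return xf + b1 + b2 - x

            xf = brentq(balance, 0.0, x, xtol=1e-30, rtol=1e-15)
            b1 = n1 * m * k1 * xf / (1 + k1 * xf)
            b2 = n2 * m * k2 * xf / (1 + k2 * xf)
            q[i] = (h1 * b1 + h2 * b2) * experiment.cell_volume * CAL_TO_UCAL
        return q

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        q = self._cumulative(theta, self.experiment)
        q_prev = np.concatenate([[0.0], q[:-1]])
        dv = np.asarray(self.experiment.injection_volumes, dtype=float)
        return q - q_prev + (dv / self.experiment.cell_volume) * (q + q_prev) / 2.0

    def fit(self) -> "TwoSiteFitResults":
        heats = self.heats
        span = float(np.max(heats) - np.min(heats))
        if span <= max(3.0 * _noise_floor(heats), 1e-9):
            raise NoBindingError("no binding detected")
        weights = _weights(self.experiment, self.exclude_first)

        def residuals(theta):
            return weights * (self._predict(theta) - self.heats)

        single = SingleSiteModel(self.experiment, self.exclude_first).fit()
        p = single.params
        lka = math.log10(p.k_a)
        inits = [
            [p.n_sites / 2, lka + 1, p.dh, p.n_sites / 2, lka - 1, p.dh],
            [p.n_sites / 2, lka + 2, p.dh, p.n_sites / 2, lka - 2, p.dh],
            [p.n_sites, lka, p.dh, p.n_sites, lka - 1.5, p.dh / 2],
        ]
        lower = [1e-2, 0.0, -1e7] * 2
        upper = [20.0, 12.0, 1e7] * 2
        best = last = None
        for theta0 in inits:
            try:
                sol = least_squares(
                    residuals,
                    np.clip(theta0, lower, upper),
                    bounds=(lower, upper),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            last = sol
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("two-site fit did not converge", last)
        return TwoSiteFitResults(self, best, weights, single)


class TwoSiteFitResults:
    """Results of the two-classes-of-sites fit, with the single-site fit
    retained for model comparison."""

    def __init__(self, model: TwoSiteModel, sol, weights, single: ITCFitResults):
        self.model = model
        self._sol = sol
        self.single = single
        n_obs = int(np.sum(weights > 0))
        self.n_obs = n_obs
        cov = _covariance(sol, n_obs, 6)
        t = model.experiment.temperature
        errs = np.sqrt(np.abs(np.diag(cov)))

        def mk(i):
            ka = 10.0 ** sol.x[3 * i + 1]
            return BindingParameters(
                n_sites=float(sol.x[3 * i]),
                k_a=float(ka),
                dh=float(sol.x[3 * i + 2]),
                temperature=t,
                n_sites_err=float(errs[3 * i]),
                k_a_err=float(abs(ka * math.log(10)) * errs[3 * i + 1]),
                dh_err=float(errs[3 * i + 2]),
            )

        # report the tighter class first
        a, b = mk(0), mk(1)
        self.site_classes = (a, b) if a.k_a >= b.k_a else (b, a)
        self.ssr = float(2.0 * sol.cost)

    @property
    def aicc(self) -> float:
        k, n = 6, self.n_obs
        aic = n * math.log(max(self.ssr / n, 1e-300)) + 2 * k
        if n - k - 1 > 0:
            aic += 2 * k * (k + 1) / (n - k - 1)
        return aic

    @property
    def delta_aicc(self) -> float:
        """AICc(two-site) - AICc(single-site); negative favors two sites."""
        return self.aicc - self.single.aicc

    @property
    def degenerate(self) -> bool:
        """True when the fit is effectively single-site: the two classes
        collapse onto each other (affinities within a factor of 3) or one
        class carries a negligible share (<5%) of the total heat capacity
        N·|ΔH|."""
        a, b = self.site_classes
        if a.k_a / b.k_a < 3.0:
            return True
        ha, hb = abs(a.n_sites * a.dh), abs(b.n_sites * b.dh)
        return min(ha, hb) < 0.05 * max(ha, hb)

    @property
    def preferred_model(self) -> str:
        return "single_site" if (self.degenerate or self.delta_aicc >= 0) else "two_site"

    def summary(self) -> str:
        a, b = self.site_classes
        return "\n".join(
            [
                "Two-sets-of-sites ITC fit",
                "=========================",
                f"class 1: N={a.n_sites:.3f}  Kd={a.k_d:.3e} M  dH={a.dh:.0f}",
                f"class 2: N={b.n_sites:.3f}  Kd={b.k_d:.3e} M  dH={b.dh:.0f}",
                f"SSR                : {self.ssr:.4g}",
                f"AICc vs single-site: {self.delta_aicc:+.2f}",
                f"degenerate classes : {self.degenerate}",
                f"preferred model    : {self.preferred_model}",
            ]
        )

    def to_dict(self) -> dict:
        a, b = self.site_classes
        return {
            "model": "two_site",
            "class1": {"N": a.n_sites, "Kd_M": a.k_d, "dH_cal_per_mol": a.dh},
            "class2": {"N": b.n_sites, "Kd_M": b.k_d, "dH_cal_per_mol": b.dh},
            "ssr": self.ssr,
            "aicc": self.aicc,
            "delta_aicc_vs_single": self.delta_aicc,
            "degenerate": self.degenerate,
            "preferred_model": self.preferred_model,
        }


# functional spellings -------------------------------------------------------


def fit_single_site(
    experiment: TitrationExperiment, exclude_first: bool = False
) -> ITCFitResults:
    return SingleSiteModel(experiment, exclude_first).fit()


def fit_two_sets_of_sites(
    experiment: TitrationExperiment, exclude_first: bool = False
) -> TwoSiteFitResults:
    return TwoSiteModel(experiment, exclude_first).fit()
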