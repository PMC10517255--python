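"""Uricase reaction kinetics: simulation, spectral decomposition, and fitting.

The uricase-catalyzed oxidation of uric acid is modelled as a sequential
first-order chain of four species,

    UA  <=>  UA2-  <=>  PIU  <=>  HIU

(urate, urate dianion, 5-peroxyisourate, 5-hydroxyisourate), with forward
rate constants ``k1, k2, k3`` and reverse constants ``k-1, k-2, k-3`` (all
reverse rates zero in the irreversible variant).  Under single-turnover
conditions (enzyme in excess of substrate) every step is pseudo-first-order,
so the concentration vector obeys a linear ODE solved exactly by the matrix
exponential.

The module also provides the spectral forward model (Beer-Lambert mixing of
per-species molar absorptivities), SVD analysis of time x wavelength
absorbance matrices with an isolated-wavelength selector, single-wavelength
chain-model fitting, Michaelis-Menten estimation, and the linear FOX-assay
standard curve used to quantify hydrogen peroxide at 595 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "SPECIES",
    "KineticModel",
    "SpeciesSpectra",
    "SpectraMatrix",
    "SVDResult",
    "MMFit",
    "FoxCurve",
    "ChainFit",
    "simulate_chain",
    "h2o2_production",
    "synthesize_spectra",
    "svd_components",
    "select_isolated_wavelength",
    "fit_chain_model",
    "fit_michaelis_menten",
    "fox_standard_curve",
    "quantify_h2o2",
    "default_species_spectra",
    "log_times",
    "EPS292_URATE",
]

#: Species of the sequential chain, in reaction order.
SPECIES = ("UA", "UA2-", "PIU", "HIU")

#: Molar extinction coefficient of urate at 292 nm (M^-1 cm^-1).
EPS292_URATE = 12650.0


@dataclass
class KineticModel:
    """Three-step sequential reaction chain with optional reverse steps.

    Parameters
    ----------
    k_forward : forward rate constants (k1, k2, k3), s^-1.
    k_reverse : reverse rate constants (k-1, k-2, k-3), s^-1. Must be all
        zero when ``reversible`` is False.
    c0 : initial concentrations of (UA, UA2-, PIU, HIU), uM.
    reversible : whether reverse steps are allowed.
    """

    k_forward: tuple[float, float, float]
    k_reverse: tuple[float, float, float] = (0.0, 0.0, 0.0)
    c0: tuple[float, float, float, float] = (25.0, 0.0, 0.0, 0.0)
    reversible: bool = True

    def __post_init__(self) -> None:
        kf = np.asarray(self.k_forward, dtype=float)
        kr = np.asarray(self.k_reverse, dtype=float)
        c0 = np.asarray(self.c0, dtype=float)
        if kf.shape != (3,) or kr.shape != (3,):
            raise ValueError("need exactly three forward and three reverse rates")
        if c0.shape != (4,):
            raise ValueError("need initial concentrations for the four species")
        if (kf < 0).any() or (kr < 0).any():
            raise ValueError("rate constants must be non-negative")
        if (c0 < 0).any():
            raise ValueError("initial concentrations must be non-negative")
        if not self.reversible and (kr != 0).any():
            raise ValueError("irreversible model requires zero reverse rates")
        self.k_forward = tuple(kf)
        self.k_reverse = tuple(kr)
        self.c0 = tuple(c0)

    def rate_matrix(self) -> np.ndarray:
        """4x4 matrix A with dc/dt = A c."""
        k1, k2, k3 = self.k_forward
        r1, r2, r3 = self.k_reverse
        return np.array(
            [
                [-k1, r1, 0.0, 0.0],
                [k1, -(r1 + k2), r2, 0.0],
                [0.0, k2, -(r2 + k3), r3],
                [0.0, 0.0, k3, -r3],
            ]
        )


@dataclass
class SpeciesSpectra:
    """Molar absorptivities epsilon(lambda) per species on a common grid.

    ``eps`` maps species name -> array of molar absorptivity (M^-1 cm^-1)
    over ``wavelengths`` (nm); ``path`` is the optical path length in cm.
    """

    wavelengths: np.ndarray
    eps: dict[str, np.ndarray]
    path: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name, e in self.eps.items():
            e = np.asarray(e, dtype=float)
            if e.shape != self.wavelengths.shape:
                raise ValueError(f"epsilon grid mismatch for species {name!r}")
            if (e < 0).any():
                raise ValueError(f"negative molar absorptivity for species {name!r}")
            self.eps[name] = e

    def matrix(self, species: tuple[str, ...] = SPECIES) -> np.ndarray:
        """Stack epsilon rows for ``species`` -> (n_species, n_wavelengths)."""
        return np.vstack([self.eps[s] for s in species])


@dataclass
class SpectraMatrix:
    """Time-resolved absorbance matrix (|times| x |wavelengths|, AU)."""

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValueError("absorbance shape must be |times| x |wavelengths|")

    def trace(self, wavelength: float) -> np.ndarray:
        """Single-wavelength kinetic trace at the grid point nearest ``wavelength``."""
        j = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.absorbance[:, j]


@dataclass
class SVDResult:
    """SVD of a spectra matrix: temporal (left) and spectral (right) vectors."""

    singular_values: np.ndarray
    temporal: np.ndarray  # columns U[:, i]
    spectral: np.ndarray  # rows Vt[i, :]
    explained_variance: np.ndarray
    wavelengths: np.ndarray
    centered: bool = False


@dataclass
class MMFit:
    """Michaelis-Menten fit result; k_cat = V_max / [E]."""

    km: float
    vmax: float
    kcat: float
    km_se: float
    vmax_se: float
    kcat_se: float
    rss: float
    enzyme_conc: float

    def rate(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.vmax * np.asarray(s, dtype=float) / (self.km + np.asarray(s, dtype=float))


@dataclass
class FoxCurve:
    """Linear A595-vs-[H2O2] standard curve for the FOX assay."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    slope: float
    intercept: float
    rvalue: float


@dataclass
class ChainFit:
    """Result of fitting the sequential chain to a single-wavelength trace."""

    rates: dict[str, float]
    stderr: dict[str, float]
    rss: float
    fitted: np.ndarray
    identifiable: bool
    flags: list[str] = field(default_factory=list)


def log_times(t_start: float = 1e-3, t_end: float = 100.0, n: int = 120) -> np.ndarray:
    """Logarithmically spaced acquisition times (s), denser at early phase."""
    return np.logspace(np.log10(t_start), np.log10(t_end), n)


def simulate_chain(model: KineticModel, times: np.ndarray) -> np.ndarray:
    """Solve the linear chain exactly; returns (|times|, 4) concentration array.

    Uses eigen-decomposition of the rate matrix when it is well conditioned,
    otherwise falls back to a per-time matrix exponential (handles repeated
    eigenvalues). Total concentration is conserved at every time point.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    A = model.rate_matrix()
    c0 = np.asarray(model.c0)
    try:
        w, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
        # repeated eigenvalues make V defective; expm is exact regardless
        diffs = np.abs(w[:, None] - w[None, :])
        np.fill_diagonal(diffs, np.inf)
        gaps = float(diffs.min())
        if not np.isfinite(cond) or cond > 1e8 or gaps < 1e-10 * (1 + np.max(np.abs(w))):
            raise np.linalg.LinAlgError
        alpha = np.linalg.solve(V, c0)
        profiles = np.real(np.exp(np.outer(times, w)) @ (V * alpha).T)
    except np.linalg.LinAlgError:
        profiles = np.vstack([linalg.expm(A * t) @ c0 for t in times])
    # tiny negative round-off from the eigen route
    tol = 1e-13 * max(1.0, float(c0.sum()))
    profiles[(profiles < 0) & (profiles > -tol)] = 0.0
    return profiles


def h2o2_production(model: KineticModel, times: np.ndarray) -> np.ndarray:
    """Cumulative hydrogen peroxide released by the PIU -> HIU step (uM).

    Peroxide is produced stoichiometrically with the forward k3 flux and is
    not consumed by the reverse step (the back reaction regenerates PIU
    without H2O2 uptake), so d[H2O2]/dt = k3 [PIU].  Computed by augmenting
    the linear system with a fifth, purely cumulative component.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    A = model.rate_matrix()
    k3 = model.k_forward[2]
    aug = np.zeros((5, 5))
    aug[:4, :4] = A
    aug[4, 2] = k3  # source term from PIU
    c0 = np.append(model.c0, 0.0)
    return np.array([(linalg.expm(aug * t) @ c0)[4] for t in times])


def synthesize_spectra(
    profiles: np.ndarray,
    times: np.ndarray,
    spectra: SpeciesSpectra,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SpectraMatrix:
    """Beer-Lambert forward model: A(t, lambda) = sum_s eps_s(lambda) c_s(t) path.

    Concentrations are in uM and epsilon in M^-1 cm^-1, so the product is
    scaled by 1e-6. Optional additive Gaussian noise with standard deviation
    ``noise_sigma`` (AU).
    """
    profiles = np.asarray(profiles, dtype=float)
    E = spectra.matrix()
    if profiles.shape[1] != E.shape[0]:
        raise ValueError("profiles and spectra species count mismatch")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    A = profiles @ E * spectra.path * 1e-6
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        A = A + rng.normal(0.0, noise_sigma, size=A.shape)
    return SpectraMatrix(times=times, wavelengths=spectra.wavelengths, absorbance=A,
                         noise_sigma=noise_sigma or None)


def svd_components(spectra: SpectraMatrix, center: bool = False) -> SVDResult:
    """SVD of the absorbance matrix, optionally after subtracting the final spectrum.

    Sign convention: each component is flipped so that its spectral entry of
    largest magnitude is positive (SVD signs are otherwise arbitrary).
    """
    A = spectra.absorbance
    if not np.isfinite(A).all():
        raise ValueError("absorbance matrix contains NaN or infinite values")
    if center:
        A = A - A[-1, :]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    for i in range(s.size):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    total = float(np.sum(s**2))
    ev = s**2 / total if total > 0 else np.zeros_like(s)
    return SVDResult(
        singular_values=s,
        temporal=U,
        spectral=Vt,
        explained_variance=ev,
        wavelengths=spectra.wavelengths,
        centered=center,
    )


def n_components_to_retain(svd: SVDResult, max_components: int = 3,
                           variance_target: float = 0.999) -> int:
    """Smaller of ``max_components`` and the count explaining ``variance_target``."""
    cum = np.cumsum(svd.explained_variance)
    by_var = int(np.searchsorted(cum, variance_target) + 1)
    return max(1, min(max_components, by_var))


def select_isolated_wavelength(svd: SVDResult, component: int = 1,
                               n_retained: int | None = None) -> float:
    """Wavelength where the chosen component dominates the kinetic signal.

    Loadings are singular-value-scaled spectral vectors s_i * v_i(lambda).
    Returns the wavelength maximizing |loading_component| / sum of the other
    retained components' |loadings|; with a single retained component, the
    wavelength of its maximal |loading|.  ``component`` is 1-based.
    """
    if n_retained is None:
        n_retained = n_components_to_retain(svd)
    if component < 1 or component > n_retained:
        raise ValueError("component index out of retained range")
    loadings = svd.singular_values[:n_retained, None] * svd.spectral[:n_retained, :]
    target = np.abs(loadings[component - 1])
    if np.all(target == 0):
        raise ValueError("degenerate component: all-zero spectral loadings")
    if n_retained == 1:
        return float(svd.wavelengths[int(np.argmax(target))])
    others = np.sum(np.abs(np.delete(loadings, component - 1, axis=0)), axis=0)
    with np.errstate(divide="ignore"):
        ratio = np.where(others > 0, target / others, np.where(target > 0, np.inf, 0.0))
    return float(svd.wavelengths[int(np.argmax(ratio))])


def _chain_trace(rates: np.ndarray, free_idx: list[int], fixed: np.ndarray,
                 times: np.ndarray, c0: tuple, eps_at_lambda: np.ndarray,
                 path: float) -> np.ndarray:
    k = fixed.copy()
    k[free_idx] = rates
    model = KineticModel(k_forward=tuple(k[:3]), k_reverse=tuple(k[3:]), c0=c0,
                         reversible=True)
    profiles = simulate_chain(model, times)
    return profiles @ eps_at_lambda * path * 1e-6


RATE_NAMES = ("k1", "k2", "k3", "k-1", "k-2", "k-3")


def fit_chain_model(
    times: np.ndarray,
    trace: np.ndarray,
    eps_at_lambda: np.ndarray,
    c0: tuple[float, float, float, float] = (25.0, 0.0, 0.0, 0.0),
    free: tuple[str, ...] = ("k1", "k2", "k3"),
    fixed_rates: dict[str, float] | None = None,
    path: float = 1.0,
    n_starts: int = 8,
) -> ChainFit:
    """Fit free rate constants of the chain to a single-wavelength trace.

    Nonlinear least squares with non-negativity bounds; multistart from
    ``n_starts`` deterministic log-spaced initial rate vectors spanning
    1/t_max .. 10/t_min, rotated across free rates so starts are not
    collinear.  Reports approximate standard errors from the Jacobian at the
    optimum, and flags non-identifiable configurations (near-zero Jacobian
    singular values relative to the largest).
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if (np.diff(times) <= 0).any():
        raise ValueError("trace times must be strictly increasing")
    eps_at_lambda = np.asarray(eps_at_lambda, dtype=float)
    fixed = np.zeros(6)
    for name, value in (fixed_rates or {}).items():
        fixed[RATE_NAMES.index(name)] = value
    free_idx = [RATE_NAMES.index(name) for name in free]
    p = len(free_idx)

    scale_lo, scale_hi = 1.0 / times[-1], 10.0 / max(times[0], 1e-6)
    grid = np.logspace(np.log10(scale_lo), np.log10(scale_hi), n_starts)
    starts = [np.array([grid[(j + i * 3) % n_starts] for i in range(p)])
              for j in range(n_starts)]

    forward_free = [i for i in free_idx if i < 3]
    reverse_free = [i for i in free_idx if i >= 3]
    if reverse_free and forward_free:
        # nested-model start: fit the irreversible subset first, then release
        # the reverse rates from zero
        sub_fixed = dict(fixed_rates or {})
        sub_fixed.update({RATE_NAMES[i]: 0.0 for i in reverse_free})
        sub = fit_chain_model(times, trace, eps_at_lambda, c0=c0,
                              free=tuple(RATE_NAMES[i] for i in forward_free),
                              fixed_rates=sub_fixed, path=path,
                              n_starts=n_starts)
        seeded = np.zeros(p)
        for pos, i in enumerate(free_idx):
            seeded[pos] = sub.rates.get(RATE_NAMES[i], 1e-6)
        seeded[seeded == 0] = 1e-6
        starts.append(seeded)

    def resid(r: np.ndarray) -> np.ndarray:
        return _chain_trace(r, free_idx, fixed, times, c0, eps_at_lambda, path) - trace

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, bounds=(0.0, np.inf),
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("all multistart fits failed")
    rss, sol = best

    flags: list[str] = []
    J = sol.jac
    sv = np.linalg.svd(J, compute_uv=False)
    identifiable = bool(sv[-1] > 1e-8 * sv[0]) if sv[0] > 0 else False
    if not identifiable:
        flags.append("non-identifiable: flat residual surface along some rate direction")
    dof = max(times.size - p, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    rates = {RATE_NAMES[i]: float(v) for i, v in zip(free_idx, sol.x)}
    stderr = {RATE_NAMES[i]: float(s) for i, s in zip(free_idx, se)}
    fitted = _chain_trace(sol.x, free_idx, fixed, times, c0, eps_at_lambda, path)
    return ChainFit(rates=rates, stderr=stderr, rss=rss, fitted=fitted,
                    identifiable=identifiable, flags=flags)


def fit_michaelis_menten(substrate: np.ndarray, rates: np.ndarray,
                         enzyme_conc: float) -> MMFit:
    """Fit v = V_max S / (K_M + S) by bounded nonlinear least squares.

    ``substrate`` in uM, ``rates`` in uM/s; k_cat = V_max / enzyme_conc (s^-1)
    with its standard error propagated from V_max.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if np.unique(s).size == 1:
        raise ValueError("all substrate concentrations are identical")
    if np.unique(s).size < 4:
        raise ValueError("need at least four distinct substrate concentrations")
    if (v < 0).any():
        raise ValueError("initial rates must be non-negative")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")

    vmax0 = float(np.max(v)) or 1.0
    km0 = float(np.median(s))
    popt, pcov = optimize.curve_fit(
        lambda S, vmax, km: vmax * S / (km + S),
        s, v, p0=[vmax0, km0],
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    vmax, km = popt
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((v - vmax * s / (km + s)) ** 2))
    return MMFit(
        km=float(km), vmax=float(vmax), kcat=float(vmax / enzyme_conc),
        km_se=float(perr[1]), vmax_se=float(perr[0]),
        kcat_se=float(perr[0] / enzyme_conc), rss=rss, enzyme_conc=enzyme_conc,
    )


def fox_standard_curve(concentrations: np.ndarray, absorbances: np.ndarray) -> FoxCurve:
    """Ordinary least-squares A595 = slope * [H2O2] + intercept."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least two distinct standard concentrations")
    res = stats.linregress(c, a)
    return FoxCurve(concentrations=c, absorbances=a, slope=float(res.slope),
                    intercept=float(res.intercept), rvalue=float(res.rvalue))


def quantify_h2o2(curve: FoxCurve, absorbances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse prediction (A - intercept)/slope; negatives clipped to 0, flagged.

    Returns (concentrations uM, clipped flag array).
    """
    if curve.slope == 0:
        raise ValueError("zero slope: standard curve cannot be inverted")
    if curve.slope < 0:
        raise ValueError("negative slope: FOX quantification requires a positive slope")
    a = np.asarray(absorbances, dtype=float)
    conc = (a - curve.intercept) / curve.slope
    clipped = conc < 0
    return np.where(clipped, 0.0, conc), clipped


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def default_species_spectra(wavelengths: np.ndarray | None = None,
                            path: float = 1.0) -> SpeciesSpectra:
    """Synthetic molar absorptivities with the urate reaction's landmarks.

    Engineered so that the urate peak sits at 292 nm with epsilon = 12,650
    M^-1 cm^-1, the product HIU peaks near 301 nm, and the PIU - HIU
    difference spectrum has a negative lobe at 294 nm and a positive lobe at
    314 nm; shapes are simple Gaussians, not measured curves.
    """
    if wavelengths is None:
        wavelengths = np.arange(250.0, 351.0, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    ua = EPS292_URATE * _gauss(wl, 292.0, 12.0)
    ua2 = 12000.0 * _gauss(wl, 295.0, 13.0)
    hiu = 11000.0 * _gauss(wl, 301.0, 12.0)
    # lobe width 6 nm keeps the two difference lobes from pulling each
    # other's extrema off the 294/314 nm landmarks
    piu = np.clip(hiu + 5000.0 * _gauss(wl, 314.0, 6.0) - 4000.0 * _gauss(wl, 294.0, 6.0), 0.0, None)
    return SpeciesSpectra(wavelengths=wl, eps={"UA": ua, "UA2-": ua2, "PIU": piu, "HIU": hiu},
                          path=path)
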