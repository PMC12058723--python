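"""EEG forward/inverse chain on an analytic concentric-spheres head model.

Sources are radial dipoles inside a three-shell (brain / skull / scalp)
concentric-spheres conductor.  The chain is: project sources to sensors
through the lead field, add structured Gaussian noise with covariance
L L^T + Lambda scaled to a target SNR, reconstruct with an array-gain
LCMV beamformer, reduce grid estimates to parcels by first-PC
extraction, and correct source leakage by innovations orthogonalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from statsmodels.tsa.api import VAR

__all__ = [
    "ForwardModel",
    "ParcelData",
    "fibonacci_sphere",
    "build_spherical_leadfield",
    "project_to_sensors",
    "sample_structured_noise",
    "scale_to_snr",
    "lcmv_beamform",
    "parcellate_pca",
    "orthogonalize_innovations",
]

DEFAULT_RADII = (0.087, 0.092, 0.100)          # brain, skull, scalp (m)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)  # S/m

_STAGES = ("source_truth", "sensor", "reconstructed", "orthogonalized")


@dataclass
class ForwardModel:
    leadfield: np.ndarray          # (n_sensors, n_sources), average-referenced
    sensor_positions: np.ndarray   # (n_sensors, 3) m
    source_positions: np.ndarray   # (n_sources, 3) m
    head_radii: tuple[float, float, float] = DEFAULT_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES

    def __post_init__(self) -> None:
        L = np.asarray(self.leadfield, dtype=float)
        if L.shape[0] < 2:
            raise ValueError("need at least 2 sensors")
        if np.any(np.linalg.norm(L, axis=0) == 0):
            raise ValueError("lead field has a zero column")
        self.leadfield = L

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]


@dataclass
class ParcelData:
    """Parcel-by-time matrix tagged with its processing stage."""

    data: np.ndarray
    fs: float
    stage: str = "source_truth"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.data = np.asarray(self.data, dtype=float)

    def advance(self, data: np.ndarray, stage: str) -> "ParcelData":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"stage may only move forward along {_STAGES}")
        return ParcelData(data=data, fs=self.fs, stage=stage)


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """n approximately uniform points on a sphere (golden-angle lattice)."""
    i = np.arange(n)
    z = 1 - 2 * (i + 0.5) / n
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z**2)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radial_dipole_coeffs(b: float, radii: np.ndarray, sigmas: np.ndarray,
                          n_terms: int) -> np.ndarray:
    """Legendre coefficients c_n of the outer-surface potential of a unit
    radial dipole at normalized eccentricity b (all radii normalized by the
    outer radius, which is 1).

    Within each shell the potential per harmonic is A r^n + B r^-(n+1);
    the innermost shell additionally carries the free-medium dipole term
    beta_n r^-(n+1) with beta_n = n b^(n-1) / (4 pi sigma_1).  Coefficients
    are fixed by potential/current continuity at the two interfaces and
    zero normal current at the scalp surface.
    """
    r1, r2 = radii[0], radii[1]
    s1, s2, s3 = sigmas
    coeffs = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        beta = n * b ** (n - 1) / (4 * np.pi * s1)
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # continuity of V at r1
        M[0] = [r1**n, -r1**n, -r1**-(n + 1), 0, 0]
        rhs[0] = -beta * r1**-(n + 1)
        # continuity of sigma dV/dr at r1
        M[1] = [s1 * n * r1**(n - 1), -s2 * n * r1**(n - 1),
                s2 * (n + 1) * r1**-(n + 2), 0, 0]
        rhs[1] = s1 * beta * (n + 1) * r1**-(n + 2)
        # continuity of V at r2
        M[2] = [0, r2**n, r2**-(n + 1), -r2**n, -r2**-(n + 1)]
        # continuity of sigma dV/dr at r2
        M[3] = [0, s2 * n * r2**(n - 1), -s2 * (n + 1) * r2**-(n + 2),
                -s3 * n * r2**(n - 1), s3 * (n + 1) * r2**-(n + 2)]
        # insulated outer boundary at r = 1
        M[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(M, rhs)
        coeffs[n] = sol[3] + sol[4]  # A3 + B3 evaluated at r = 1
    return coeffs


def build_spherical_leadfield(sensor_positions: np.ndarray,
                              source_positions: np.ndarray,
                              radii: tuple[float, float, float] = DEFAULT_RADII,
                              conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
                              n_terms: int = 60) -> ForwardModel:
    """Average-referenced lead field for radial unit dipoles.

    Sensors must lie on the outer shell; sources strictly inside the
    innermost shell.  The truncated Legendre series converges rapidly for
    sources at moderate eccentricity.  Potentials are in arbitrary units
    proportional to V/(A m); the overall scale cancels downstream.
    """
    sens = np.asarray(sensor_positions, dtype=float)
    srcs = np.asarray(source_positions, dtype=float)
    radii_arr = np.asarray(radii, dtype=float)
    sigmas = np.asarray(conductivities, dtype=float)
    R = radii_arr[-1]
    if np.any(np.linalg.norm(srcs, axis=1) >= radii_arr[0]):
        raise ValueError("all sources must lie strictly inside the innermost shell")
    if not np.allclose(np.linalg.norm(sens, axis=1), R, rtol=1e-6):
        raise ValueError("sensors must lie on the outer shell")
    norm_radii = radii_arr / R
    L = np.empty((sens.shape[0], srcs.shape[0]))
    sens_unit = sens / np.linalg.norm(sens, axis=1, keepdims=True)
    ecc = np.linalg.norm(srcs, axis=1) / R
    coeff_cache: dict[float, np.ndarray] = {}
    for j in range(srcs.shape[0]):
        b = round(float(ecc[j]), 12)
        if b not in coeff_cache:
            coeff_cache[b] = _radial_dipole_coeffs(b, norm_radii, sigmas, n_terms)
        src_unit = srcs[j] / np.linalg.norm(srcs[j])
        cosg = np.clip(sens_unit @ src_unit, -1.0, 1.0)
        L[:, j] = npleg.legval(cosg, coeff_cache[b]) / R**2
    L -= L.mean(axis=0, keepdims=True)  # average reference
    return ForwardModel(leadfield=L, sensor_positions=sens, source_positions=srcs,
                        head_radii=tuple(radii), conductivities=tuple(conductivities))


def project_to_sensors(sources: np.ndarray, fm: ForwardModel) -> np.ndarray:
    """Sensor-space data: exact product L @ sources (no noise)."""
    sources = np.asarray(sources, dtype=float)
    if sources.shape[0] != fm.n_sources:
        raise ValueError("source count does not match lead field")
    return fm.leadfield @ sources


def structured_noise_covariance(fm: ForwardModel, sensor_signal: np.ndarray) -> np.ndarray:
    """C_n = L L^T + Lambda with Lambda_ii = 0.1 * var(signal_i)."""
    lam = 0.1 * np.var(np.asarray(sensor_signal, dtype=float), axis=1)
    return fm.leadfield @ fm.leadfield.T + np.diag(lam)


def sample_structured_noise(fm: ForwardModel, sensor_signal: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise, i.i.d. across time, covariance L L^T + Lambda.

    The L L^T term is spatially structured "biological" noise (sources
    everywhere project through the same head model); the diagonal term is
    instrumental noise proportional to each sensor's signal variance.
    """
    sensor_signal = np.asarray(sensor_signal, dtype=float)
    if sensor_signal.size == 0 or not np.any(sensor_signal):
        raise ValueError("sensor_signal must be nonzero")
    C = structured_noise_covariance(fm, sensor_signal)
    try:
        chol = np.linalg.cholesky(C + 1e-12 * np.trace(C) / C.shape[0] * np.eye(C.shape[0]))
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance is not positive semi-definite") from err
    return chol @ rng.standard_normal((fm.n_sensors, sensor_signal.shape[1]))


def scale_to_snr(sensor: np.ndarray, noise: np.ndarray,
                 snr_db: float) -> tuple[float, np.ndarray]:
    """Scale `noise` by gamma so that 10 log10(var(sensor)/var(gamma noise))
    equals `snr_db`, with variance pooled over sensors and samples.

    Returns (gamma, sensor + gamma * noise).
    """
    sensor = np.asarray(sensor, dtype=float)
    noise = np.asarray(noise, dtype=float)
    v_noise = np.var(noise)
    if v_noise == 0:
        raise ValueError("noise has zero variance")
    gamma = float(np.sqrt(np.var(sensor) / (v_noise * 10 ** (snr_db / 10.0))))
    return gamma, sensor + gamma * noise


def lcmv_beamform(noisy_sensor: np.ndarray, fm: ForwardModel,
                  reg_fraction: float = 0.05) -> np.ndarray:
    """Array-gain LCMV source reconstruction.

    The sensor covariance is regularized by reg_fraction of the average
    sensor power on the diagonal; lead-field columns are normalized to
    unit norm (array gain) before computing w = C^-1 l / (l^T C^-1 l).
    """
    X = np.asarray(noisy_sensor, dtype=float)
    if X.shape[0] != fm.n_sensors:
        raise ValueError("sensor data does not match lead field")
    C = np.cov(X)
    n = C.shape[0]
    Creg = C + reg_fraction * (np.trace(C) / n) * np.eye(n)
    Lt = fm.leadfield / np.linalg.norm(fm.leadfield, axis=0, keepdims=True)
    try:
        CiL = np.linalg.solve(Creg, Lt)
    except np.linalg.LinAlgError as err:
        raise ValueError("regularized covariance is singular") from err
    denom = np.einsum("ij,ij->j", Lt, CiL)
    W = CiL / denom  # (n_sensors, n_sources)
    return W.T @ X


def parcellate_pca(grid_estimates: np.ndarray, parcel_assignment: np.ndarray,
                   fs: float = 1.0, stage: str = "reconstructed") -> ParcelData:
    """Reduce grid time courses to one course per parcel via the first PC.

    The PC is sign-aligned so its correlation with the mean member time
    course is non-negative; single-member parcels pass through up to that
    sign convention.
    """
    X = np.asarray(grid_estimates, dtype=float)
    parcels = np.asarray(parcel_assignment)
    ids = np.unique(parcels)
    out = np.empty((ids.size, X.shape[1]))
    for i, pid in enumerate(ids):
        members = X[parcels == pid]
        if members.shape[0] == 0:
            raise ValueError(f"parcel {pid} has no member locations")
        if members.shape[0] == 1:
            pc = members[0].copy()
        else:
            centered = members - members.mean(axis=1, keepdims=True)
            # first left singular vector = first PC over member courses
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            pc = s[0] * vt[0]
        mean_course = members.mean(axis=0)
        if np.dot(pc - pc.mean(), mean_course - mean_course.mean()) < 0:
            pc = -pc
        out[i] = pc
    return ParcelData(data=out, fs=fs, stage=stage)


def orthogonalize_innovations(parcels: ParcelData, ar_order: int = 5,
                              eig_floor: float = 0.05,
                              return_model: bool = False):
    """Leakage correction by orthogonalizing multivariate AR innovations.

    Fits a VAR(ar_order) to the parcel courses, whitens the innovation
    *correlation* matrix with a symmetric (ZCA) inverse square root
    (variances preserved; already-uncorrelated innovations pass through
    unchanged), and re-filters the orthogonalized innovations through the
    fitted AR model.  The first ar_order samples are kept from the input
    as initial conditions.

    Beamformed parcel data can have a nearly rank-deficient innovation
    correlation (more parcels than effective sensor dimensions); its
    eigenvalues are floored at `eig_floor` before inversion so the
    whitening cannot amplify near-null directions.  Directions above the
    floor are whitened exactly.
    """
    X = parcels.data
    P, T = X.shape
    if T <= P * ar_order + ar_order:
        raise ValueError("too few samples to fit the VAR model")
    res = VAR(X.T).fit(maxlags=ar_order, trend="n")
    A = _stabilize_var(res.coefs)  # (p, P, P)
    resid = X.T[ar_order:] - _var_predict(A, X.T)
    mu = resid.mean(axis=0)
    r0 = resid - mu
    C = (r0.T @ r0) / r0.shape[0]
    d = np.sqrt(np.diag(C))
    if np.any(d == 0):
        raise ValueError("degenerate innovation variance")
    corr = C / np.outer(d, d)
    evals, evecs = np.linalg.eigh(corr)
    if evals.max() <= 0:
        raise ValueError("innovation correlation matrix is singular")
    evals = np.maximum(evals, eig_floor)
    corr_isqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    Wz = np.diag(d) @ corr_isqrt @ np.diag(1.0 / d)  # correlation-ZCA
    e = r0 @ Wz.T + mu  # diagonal zero-lag covariance by construction
    p = ar_order
    Y = np.empty_like(X)
    Y[:, :p] = X[:, :p]
    for t in range(p, T):
        acc = e[t - p].copy()
        for i in range(p):
            acc += A[i] @ Y[:, t - 1 - i]
        Y[:, t] = acc
    out = parcels.advance(Y, "orthogonalized")
    if return_model:
        return out, {"ar_coefs": A, "innovations": e}
    return out


def _var_predict(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """One-step VAR predictions for rows ar_order..T-1 of X (time-major)."""
    p = A.shape[0]
    T = X.shape[0]
    pred = np.zeros((T - p, X.shape[1]))
    for i in range(p):
        pred += X[p - 1 - i:T - 1 - i] @ A[i].T
    return pred


def _stabilize_var(A: np.ndarray, margin: float = 0.999) -> np.ndarray:
    """Shrink AR coefficients until the companion spectral radius < margin.

    A least-squares VAR fit can be marginally unstable on narrowband
    data; re-filtering new innovations through an unstable model
    diverges, so lag-i coefficients are scaled by rho^i with rho chosen
    to pull the companion eigenvalues inside the unit circle (leaves
    stable fits untouched).
    """
    p, P, _ = A.shape
    comp = np.zeros((p * P, p * P))
    comp[:P] = np.hstack(list(A))
    if p > 1:
        comp[P:, :-P] = np.eye((p - 1) * P)
    radius = np.max(np.abs(np.linalg.eigvals(comp)))
    if radius < margin:
        return A
    rho = margin / radius
    return np.array([A[i] * rho ** (i + 1) for i in range(p)])


def var_innovations(data: np.ndarray, ar_order: int = 5) -> np.ndarray:
    """Residuals of a freshly fitted VAR(ar_order); rows are time points."""
    return VAR(np.asarray(data, dtype=float).T).fit(maxlags=ar_order, trend="n").resid
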