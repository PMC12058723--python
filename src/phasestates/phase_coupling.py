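"""State-dependent phase coupling via analytic-signal surgery.

During each occurrence of a state, every coupled target source is
rewritten as  y_j(t) = A_j(t) cos(theta_i(t) + dphi + eps) : its own
Hilbert envelope carrying the driver's instantaneous phase shifted by
the edge's target phase difference plus a per-occurrence Gaussian jitter
eps ~ N(0, std_pd^2).  Amplitudes are taken from the original target and
phases from the original driver, so drivers are never modified and
instantaneous amplitude is preserved exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .markov_states import StateCouplingSpec, StateSequence
from .oscillators import SourceSignals

__all__ = ["CoupledSignals", "analytic_signal", "apply_coupling"]


@dataclass
class CoupledSignals:
    """Coupled source matrix plus the realized per-occurrence jitters.

    jitter_log rows are (occurrence_index, state, start, end, driver,
    target, delta_phi, eps).
    """

    data: np.ndarray  # (P, T)
    fs: float
    jitter_log: list[dict] = field(default_factory=list)

    def as_sources(self) -> SourceSignals:
        return SourceSignals(data=self.data, fs=self.fs)


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal x + i H(x) along the last axis.

    The real part equals the input exactly; modulus and argument are the
    instantaneous amplitude and phase.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN/Inf")
    z = hilbert(x, axis=-1)
    # scipy's FFT round-trip perturbs the real part at machine precision;
    # restore the exact identity Re(z) = x
    return x + 1j * z.imag


def apply_coupling(sources: SourceSignals, seq: StateSequence,
                   specs: list[StateCouplingSpec], std_pd: float,
                   rng: np.random.Generator) -> CoupledSignals:
    """Inject the per-state phase couplings into `sources`.

    Envelopes and driver phases are computed once from the full original
    session (avoids Hilbert edge artifacts inside short occurrences).
    The jitter eps is drawn once per (occurrence, edge).  Sources never
    targeted, and samples outside occurrences of a coupled state, are
    bit-identical to the input.
    """
    if std_pd < 0:
        raise ValueError("std_pd must be >= 0")
    by_state = {s.state: s for s in specs}
    missing = set(np.unique(seq.labels)) - set(by_state)
    if missing:
        raise ValueError(f"no coupling spec for states {sorted(missing)}")
    P, T = sources.data.shape
    if seq.n_samples != T:
        raise ValueError("state sequence length does not match sources")
    for s in specs:
        for drv, tgt, _ in s.edges:
            if not (0 <= drv < P and 0 <= tgt < P):
                raise ValueError("edge references out-of-range source")
    z = analytic_signal(sources.data)
    envelope = np.abs(z)
    phase = np.angle(z)
    out = sources.data.copy()
    log: list[dict] = []
    for occ_idx, (state, start, end) in enumerate(seq.occurrences):
        for drv, tgt, dphi in by_state[state].edges:
            eps = float(rng.normal(0.0, std_pd)) if std_pd > 0 else 0.0
            out[tgt, start:end] = envelope[tgt, start:end] * np.cos(
                phase[drv, start:end] + dphi + eps)
            log.append(dict(occurrence=occ_idx, state=state, start=start, end=end,
                            driver=drv, target=tgt, delta_phi=dphi, eps=eps))
    return CoupledSignals(data=out, fs=sources.fs, jitter_log=log)
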