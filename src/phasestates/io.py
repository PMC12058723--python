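"""HDF5/JSON persistence for sessions and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .markov_states import StateSequence, StateCouplingSpec
from .oscillators import SourceSignals

__all__ = ["save_signals", "load_signals", "save_signals_csv",
           "save_ground_truth", "load_ground_truth",
           "save_leadfield", "load_leadfield",
           "save_hmm_model", "load_hmm_model", "save_state_path"]


def save_signals(path: str | Path, signals: SourceSignals) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=signals.data)
        f.create_dataset("fs", data=signals.fs)
        f.create_dataset("labels", data=np.array(signals.labels, dtype="S"))


def load_signals(path: str | Path) -> SourceSignals:
    with h5py.File(path, "r") as f:
        return SourceSignals(data=f["data"][()], fs=float(f["fs"][()]),
                             labels=[s.decode() for s in f["labels"][()]])


def save_ground_truth(path: str | Path, seq: StateSequence,
                      specs: list[StateCouplingSpec]) -> None:
    payload = {
        "n_states": seq.n_states,
        "labels": seq.labels.tolist(),
        "occurrences": [list(o) for o in seq.occurrences],
        "coupling_specs": [
            {"state": s.state, "edges": [[d, t, phi] for d, t, phi in s.edges]}
            for s in specs
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> tuple[StateSequence, list[StateCouplingSpec]]:
    payload = json.loads(Path(path).read_text())
    seq = StateSequence(labels=np.array(payload["labels"], dtype=np.int64),
                        n_states=payload["n_states"],
                        occurrences=[tuple(o) for o in payload["occurrences"]])
    specs = [StateCouplingSpec(state=s["state"],
                               edges=[(int(d), int(t), float(phi)) for d, t, phi in s["edges"]])
             for s in payload["coupling_specs"]]
    return seq, specs


def save_signals_csv(path: str | Path, signals: SourceSignals) -> None:
    """Plain-text export for tiny fixtures (one row per source)."""
    header = f"fs={signals.fs};labels=" + ",".join(signals.labels)
    np.savetxt(path, signals.data, delimiter=",", header=header)


def save_hmm_model(path: str | Path, model) -> None:
    """Serialize a fitted HMM (transitions, covariances, EM trace)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("transition_matrix", data=model.transition_matrix)
        f.create_dataset("initial_probs", data=model.initial_probs)
        f.create_dataset("state_covariances", data=model.state_covariances)
        f.create_dataset("fit_log", data=np.asarray(model.fit_log, dtype=float))
        f.attrs["n_states"] = model.n_states
        if model.seed is not None:
            f.attrs["seed"] = model.seed


def load_hmm_model(path: str | Path):
    from .hmm_inference import HMMModel

    with h5py.File(path, "r") as f:
        return HMMModel(
            n_states=int(f.attrs["n_states"]),
            transition_matrix=f["transition_matrix"][()],
            initial_probs=f["initial_probs"][()],
            state_covariances=f["state_covariances"][()],
            fit_log=list(f["fit_log"][()]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_state_path(path: str | Path, stc) -> None:
    """Decoded path as CSV: original sample index, state."""
    idx = np.arange(stc.path.size) + stc.offset
    np.savetxt(path, np.column_stack([idx, stc.path]), fmt="%d",
               delimiter=",", header="sample,state")


def save_leadfield(path: str | Path, leadfield: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("leadfield", data=np.asarray(leadfield, dtype=float))


def load_leadfield(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["leadfield"][()]
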