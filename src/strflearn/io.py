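"""HDF5 persistence for spectrograms, patch matrices, whitening models, and ensembles."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .audspec import AuditorySpectrogram
from .learning import ObjectiveConfig, STRFEnsemble, TraceRecord
from .patches import PatchMatrix, WhiteningModel


def save_similarity(path, W) -> None:
    from .clustering import SimilarityMatrix

    M = W.W if isinstance(W, SimilarityMatrix) else np.asarray(W)
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=M, compression="gzip")


def load_similarity(path):
    from .clustering import SimilarityMatrix

    with h5py.File(path, "r") as f:
        return SimilarityMatrix(W=f["W"][...])


def save_mtf(path, mtf) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=mtf.magnitude, compression="gzip")
        f.create_dataset("rates_hz", data=mtf.rates_hz)
        f.create_dataset("scales_cpo", data=mtf.scales_cpo)


def load_mtf(path):
    from .strfmetrics import ModulationTransferFunction

    with h5py.File(path, "r") as f:
        return ModulationTransferFunction(
            magnitude=f["magnitude"][...],
            rates_hz=f["rates_hz"][...],
            scales_cpo=f["scales_cpo"][...],
        )


def save_contours(path, contours) -> None:
    """Contour polylines as JSON: a list of [[rate_hz, scale_cpo], ...]."""
    with open(path, "w") as f:
        json.dump([np.asarray(c).tolist() for c in contours], f)


def save_spectrogram(path, spec: AuditorySpectrogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=spec.values, compression="gzip")
        f.create_dataset("center_freqs_hz", data=spec.center_freqs_hz)
        f.attrs["frame_ms"] = spec.frame_ms


def load_spectrogram(path) -> AuditorySpectrogram:
    with h5py.File(path, "r") as f:
        return AuditorySpectrogram(
            values=f["values"][...],
            center_freqs_hz=f["center_freqs_hz"][...],
            frame_ms=float(f.attrs["frame_ms"]),
        )


def save_patches(path, pm: PatchMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=pm.X, compression="gzip")
        f.attrs["hop_ms"] = pm.hop_ms
        f.attrs["preprocessed"] = pm.preprocessed
        if pm.patch_shape is not None:
            f.attrs["patch_shape"] = pm.patch_shape


def load_patches(path) -> PatchMatrix:
    with h5py.File(path, "r") as f:
        shape = tuple(f.attrs["patch_shape"]) if "patch_shape" in f.attrs else None
        return PatchMatrix(
            X=f["X"][...],
            patch_shape=shape,
            hop_ms=float(f.attrs["hop_ms"]),
            preprocessed=bool(f.attrs["preprocessed"]),
        )


def save_whitening(path, model: WhiteningModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eigvecs", data=model.eigvecs, compression="gzip")
        f.create_dataset("eigvals", data=model.eigvals)
        f.attrs["var_fraction_target"] = model.var_fraction_target
        f.attrs["var_captured"] = model.var_captured


def load_whitening(path) -> WhiteningModel:
    with h5py.File(path, "r") as f:
        return WhiteningModel(
            eigvecs=f["eigvecs"][...],
            eigvals=f["eigvals"][...],
            var_fraction_target=float(f.attrs["var_fraction_target"]),
            var_captured=float(f.attrs["var_captured"]),
        )


def save_ensemble(path, ens: STRFEnsemble, trace: TraceRecord | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=ens.filters, compression="gzip")
        if ens.strfs is not None:
            f.create_dataset("strfs", data=ens.strfs, compression="gzip")
        f.attrs["coordinate_space"] = ens.coordinate_space
        f.attrs["constraint_mode"] = ens.constraint_mode
        f.attrs["seed"] = ens.seed
        f.attrs["objective"] = json.dumps(
            {"kind": ens.objective.kind, "N_ms": ens.objective.N_ms, "frame_ms": ens.objective.frame_ms}
        )
        if ens.patch_shape is not None:
            f.attrs["patch_shape"] = ens.patch_shape
        if trace is not None:
            g = f.create_group("trace")
            g.create_dataset("objectives", data=np.asarray(trace.objectives))
            g.create_dataset("residuals", data=np.asarray(trace.residuals))
            g.create_dataset("halvings", data=np.asarray(trace.halvings))
            g.attrs["stop_reason"] = trace.stop_reason


def load_ensemble(path):
    with h5py.File(path, "r") as f:
        obj = json.loads(f.attrs["objective"])
        ens = STRFEnsemble(
            filters=f["filters"][...],
            coordinate_space=str(f.attrs["coordinate_space"]),
            constraint_mode=str(f.attrs["constraint_mode"]),
            objective=ObjectiveConfig(**obj),
            seed=int(f.attrs["seed"]),
            patch_shape=tuple(f.attrs["patch_shape"]) if "patch_shape" in f.attrs else None,
            strfs=f["strfs"][...] if "strfs" in f else None,
        )
        trace = None
        if "trace" in f:
            g = f["trace"]
            trace = TraceRecord(
                objectives=list(g["objectives"][...]),
                residuals=list(g["residuals"][...]),
                halvings=list(g["halvings"][...]),
                stop_reason=str(g.attrs["stop_reason"]),
            )
        return ens, trace
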