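"""HDF5 serialization of k-space containers, phantoms and reconstructions.

Layout per k-space dataset (one group per b-value under ``/kspace``):
``data`` (complex), ``traj/shot_lines``, ``traj/line_time``, ``traj/delta_te``
and attributes ``matrix``, ``echo_spacing``, ``bvalue``. Phantom ground truth
lives under ``/truth``.
"""
from __future__ import annotations

from typing import Dict

import h5py
import numpy as np

from .encoding import ChemShiftEncodedKSpace, EPITrajectory, ShotPhaseMaps, WaterFatImage
from .simulator import PhantomGroundTruth


def _write_traj(grp: h5py.Group, traj: EPITrajectory) -> None:
    tg = grp.create_group("traj")
    lines = np.stack([traj.shot_lines(l) for l in range(traj.num_shots)]) \
        if len({len(traj.shot_lines(l)) for l in range(traj.num_shots)}) == 1 else None
    if lines is not None:
        tg.create_dataset("shot_lines", data=lines)
    else:  # ragged interleaves stored per shot
        for l in range(traj.num_shots):
            tg.create_dataset(f"shot_lines_{l}", data=traj.shot_lines(l))
    tg.create_dataset("line_time", data=traj.line_times)
    tg.create_dataset("delta_te", data=np.asarray(traj.delta_te))
    grp.attrs["matrix"] = traj.matrix
    grp.attrs["echo_spacing"] = traj.echo_spacing
    grp.attrs["num_shots"] = traj.num_shots


def _read_traj(grp: h5py.Group) -> EPITrajectory:
    return EPITrajectory(
        matrix=tuple(int(v) for v in grp.attrs["matrix"]),
        num_shots=int(grp.attrs["num_shots"]),
        delta_te=tuple(float(v) for v in grp["traj/delta_te"][()]),
        echo_spacing=float(grp.attrs["echo_spacing"]),
    )


def save_kspace(path, kspaces: Dict[float, ChemShiftEncodedKSpace], truth: PhantomGroundTruth | None = None) -> None:
    """Write per-b-value k-space data (and optionally the ground truth)."""
    with h5py.File(path, "w") as f:
        root = f.create_group("kspace")
        for b, ks in kspaces.items():
            grp = root.create_group(f"b{int(b)}")
            grp.create_dataset("data", data=ks.data)
            grp.attrs["bvalue"] = float(b)
            _write_traj(grp, ks.trajectory)
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("water", data=truth.water)
            tg.create_dataset("fat", data=truth.fat)
            tg.create_dataset("b0_map", data=truth.b0_map)
            tg.create_dataset("csm", data=truth.csm)
            tg.create_dataset("adc_map", data=truth.adc_map)
            tg.attrs["bvalues"] = list(truth.bvalues)
            tg.attrs["noise_sigma"] = truth.noise_sigma
            tg.attrs["seed"] = truth.seed
            pg = tg.create_group("true_phases")
            for b, ph in truth.true_phases.items():
                pg.create_dataset(f"b{int(b)}", data=ph.phases)


def load_kspace(path) -> Dict[float, ChemShiftEncodedKSpace]:
    out: Dict[float, ChemShiftEncodedKSpace] = {}
    with h5py.File(path, "r") as f:
        for name, grp in f["kspace"].items():
            traj = _read_traj(grp)
            b = float(grp.attrs["bvalue"])
            out[b] = ChemShiftEncodedKSpace(grp["data"][()], traj, bvalue=b)
    return out


def load_truth(path) -> PhantomGroundTruth:
    with h5py.File(path, "r") as f:
        tg = f["truth"]
        phases = {
            float(name[1:]): ShotPhaseMaps(ds[()])
            for name, ds in tg["true_phases"].items()
        }
        return PhantomGroundTruth(
            water=tg["water"][()],
            fat=tg["fat"][()],
            b0_map=tg["b0_map"][()],
            csm=tg["csm"][()],
            true_phases=phases,
            bvalues=tuple(float(b) for b in tg.attrs["bvalues"]),
            adc_map=tg["adc_map"][()],
            noise_sigma=float(tg.attrs["noise_sigma"]),
            seed=int(tg.attrs["seed"]),
        )


def save_reconstruction(path, results: Dict[float, tuple]) -> None:
    """Write per-b-value (WaterFatImage, ShotPhaseMaps, diagnostics) tuples."""
    with h5py.File(path, "w") as f:
        for b, (wf, phases, diag) in results.items():
            grp = f.create_group(f"b{int(b)}")
            grp.create_dataset("water", data=wf.water)
            grp.create_dataset("fat", data=wf.fat)
            grp.create_dataset("phases", data=phases.phases)
            grp.attrs["bvalue"] = float(b)
            grp.attrs["residuals"] = [float(r) for r in diag.get("residuals", [])]
            grp.attrs["iterations"] = int(diag.get("iterations", 0))


def load_reconstruction(path) -> Dict[float, tuple]:
    out = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            b = float(grp.attrs["bvalue"])
            wf = WaterFatImage(grp["water"][()], grp["fat"][()])
            phases = ShotPhaseMaps(grp["phases"][()])
            diag = {
                "residuals": list(grp.attrs.get("residuals", [])),
                "iterations": int(grp.attrs.get("iterations", 0)),
            }
            out[b] = (wf, phases, diag)
    return out
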