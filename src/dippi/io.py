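"""File formats and small image utilities.

Complex data travel as magnitude/phase NIfTI pairs (the form scanners
export); gradient tables use the FSL bval/bvec dialect plus a TSV
acquisition table carrying t_phase, readout type and head-orientation id
per volume. b values are canonically ms/um^2 (s/mm^2 inputs are converted
automatically).
"""

from __future__ import annotations

import logging

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionVolume, Scheme

__all__ = [
    "read_complex_series",
    "write_complex_series",
    "read_scheme",
    "volumes_to_scheme",
    "frequency_gradient_map",
]

log = logging.getLogger("dippi")


def read_complex_series(magnitude_path, phase_path):
    """Load a magnitude/phase NIfTI pair as a complex array.

    Phase stored as scaled integers (e.g. the [-4096, 4096] convention) is
    rescaled to (-pi, pi] with a logged warning. Returns (complex array,
    affine, header of the magnitude image).
    """
    mag_img = nib.load(str(magnitude_path))
    try:
        phs_img = nib.load(str(phase_path))
    except FileNotFoundError as err:
        raise FileNotFoundError(
            f"phase image {phase_path} not found (complex data need a "
            "magnitude/phase pair)") from err
    mag = np.asarray(mag_img.dataobj, dtype=float)
    phs = np.asarray(phs_img.dataobj, dtype=float)
    if mag.shape != phs.shape:
        raise ValueError(
            f"magnitude shape {mag.shape} != phase shape {phs.shape}")
    if not np.allclose(mag_img.affine, phs_img.affine, atol=1e-4):
        raise ValueError("magnitude and phase affines differ")
    pmax = np.abs(phs).max() if phs.size else 0.0
    if pmax > np.pi * (1 + 1e-6):
        scale = np.pi / 4096.0 if pmax <= 4096 * (1 + 1e-6) else np.pi / pmax
        log.warning(
            "phase range (max |phi| = %.1f) exceeds pi: rescaling by %g "
            "assuming scaled-integer storage", pmax, scale)
        phs = phs * scale
    return mag * np.exp(1j * phs), mag_img.affine, mag_img.header


def write_complex_series(data, affine, magnitude_path, phase_path):
    """Write a complex array as a magnitude/phase NIfTI pair (radians)."""
    data = np.asarray(data)
    nib.save(nib.Nifti1Image(np.abs(data).astype(np.float64), affine),
             str(magnitude_path))
    nib.save(nib.Nifti1Image(np.angle(data).astype(np.float64), affine),
             str(phase_path))


def read_scheme(bval_path, bvec_path, table_path, TE1: float = 50.0,
                TE2: float = 70.0):
    """Parse FSL bval/bvec files plus the per-volume acquisition table.

    The table (TSV) needs columns ``t_phase`` (ms) and ``readout``
    (SE/ASE), one row per volume in file order; an ``orientation`` column
    is optional. b values above 100 are taken as s/mm^2 and converted to
    ms/um^2 (logged). Returns the list of :class:`AcquisitionVolume`.
    """
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    bvecs = bvecs.reshape(-1, 3)
    if bvals.size != bvecs.shape[0]:
        raise ValueError("bval / bvec length mismatch")
    if np.nanmax(bvals) > 100:
        log.info("b values look like s/mm^2; converting to ms/um^2")
        bvals = bvals * 1e-3
    table = pd.read_csv(str(table_path), sep=r"\s+|,|\t", engine="python")
    if len(table) != bvals.size:
        raise ValueError(
            f"table has {len(table)} rows for {bvals.size} volumes")
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any((bvals > 0) & (norms < 1e-6)):
        raise ValueError("zero gradient vector with b > 0")
    bvecs = np.where(norms[:, None] > 1e-6, bvecs / np.where(
        norms[:, None] > 1e-6, norms[:, None], 1.0), bvecs)
    volumes = []
    for i in range(bvals.size):
        row = table.iloc[i]
        volumes.append(AcquisitionVolume(
            b=float(bvals[i]), g_hat=bvecs[i],
            t_phase=float(row["t_phase"]),
            readout=str(row["readout"]).upper(), TE1=TE1, TE2=TE2,
            orientation_id=int(row.get("orientation", 0)),
        ))
    return volumes


def volumes_to_scheme(volumes) -> tuple[Scheme, np.ndarray, np.ndarray]:
    """Pair SE and ASE volumes into a per-excitation :class:`Scheme`.

    Volumes are matched on (b, gradient, t_phase, orientation) in file
    order. Returns (scheme, se_indices, ase_indices) mapping excitations
    back to volume positions.
    """
    def key(v):
        return (round(v.b, 6), tuple(np.round(v.g_hat, 6)),
                round(v.t_phase, 6), v.orientation_id)

    se = [(i, v) for i, v in enumerate(volumes) if v.readout == "SE"]
    ase = {key(v): [] for _, v in se}
    for i, v in enumerate(volumes):
        if v.readout == "ASE":
            if key(v) not in ase:
                raise ValueError(f"ASE volume {i} has no SE partner")
            ase[key(v)].append(i)
    se_idx, ase_idx = [], []
    for i, v in se:
        partners = ase[key(v)]
        if not partners:
            raise ValueError(f"SE volume {i} has no ASE partner")
        se_idx.append(i)
        ase_idx.append(partners.pop(0))
    vols = [volumes[i] for i in se_idx]
    scheme = Scheme(
        [v.b for v in vols], [v.g_hat for v in vols],
        [volumes[j].t_phase for j in ase_idx],
        vols[0].TE1, vols[0].TE2,
        B0_hat=[v.B0_hat for v in vols],
        orientation_id=[v.orientation_id for v in vols],
    )
    return scheme, np.array(se_idx), np.array(ase_idx)


def frequency_gradient_map(phase, TE: float, voxel_size=(1.0, 1.0, 1.0)):
    """Frequency map (Hz) and its spatial-gradient magnitude (Hz/mm).

    The phase image (radians, already unwrapped) is divided by the echo
    time ``TE`` (ms); the gradient uses central differences scaled by the
    voxel size (mm).
    """
    if TE <= 0:
        raise ValueError("TE must be positive")
    phase = np.asarray(phase, float)
    freq = phase / (TE * 1e-3) / (2 * np.pi)  # Hz
    grads = np.gradient(freq, *voxel_size[:phase.ndim])
    if phase.ndim == 1:
        grads = [grads]
    gmag = np.sqrt(sum(g**2 for g in grads))
    return freq, gmag
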