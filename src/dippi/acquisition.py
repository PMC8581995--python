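"""Acquisition schemes for diffusion-prepared phase imaging.

Each excitation produces two echo-planar readouts: a spin echo (SE) at the
first effective echo time and an asymmetric spin echo (ASE) offset from the
second spin echo by the phase-accumulation time ``t_phase``. The scheme is
stored per excitation (one row per b / gradient / t_phase combination);
:meth:`Scheme.volumes` expands it into the per-readout volume list used by
the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["AcquisitionVolume", "Scheme", "fibonacci_directions"]

Z_HAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class AcquisitionVolume:
    """One readout volume of a DIPPI acquisition."""

    b: float  # ms/um^2
    g_hat: np.ndarray  # unit gradient direction (zero allowed for b=0)
    t_phase: float  # ms (irrelevant for SE readouts)
    readout: str  # "SE" or "ASE"
    TE1: float  # ms
    TE2: float  # ms
    B0_hat: np.ndarray = field(default_factory=lambda: Z_HAT.copy())
    orientation_id: int = 0

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.readout not in ("SE", "ASE"):
            raise ValueError("readout must be 'SE' or 'ASE'")
        g = np.asarray(self.g_hat, dtype=float)
        n = np.linalg.norm(g)
        if self.b > 0 and abs(n - 1.0) > 1e-6:
            raise ValueError("gradient direction must be unit-norm for b > 0")
        if self.readout == "ASE" and not self.t_phase >= 0:
            raise ValueError("ASE volumes need a finite t_phase >= 0")


class Scheme:
    """A DIPPI acquisition: paired SE/ASE readouts per excitation.

    Parameters are arrays over excitations: ``b`` (ms/um^2), ``bvecs``
    (n, 3) unit gradients (zero rows for b=0), ``t_phase`` (ms),
    ``B0_hat`` (n, 3) main-field direction per excitation in the image
    frame (varies with head orientation), ``orientation_id`` integer label
    of the head position, and scalar effective echo times TE1/TE2 (ms).
    """

    def __init__(self, b, bvecs, t_phase, TE1=50.0, TE2=70.0,
                 B0_hat=None, orientation_id=None):
        self.b = np.atleast_1d(np.asarray(b, dtype=float))
        n = self.b.size
        self.bvecs = np.asarray(bvecs, dtype=float).reshape(n, 3)
        self.t_phase = np.broadcast_to(
            np.asarray(t_phase, dtype=float), (n,)).copy()
        self.TE1 = float(TE1)
        self.TE2 = float(TE2)
        if B0_hat is None:
            B0_hat = Z_HAT
        self.B0_hat = np.broadcast_to(
            np.asarray(B0_hat, dtype=float), (n, 3)).copy()
        if orientation_id is None:
            orientation_id = np.zeros(n, dtype=int)
        self.orientation_id = np.broadcast_to(
            np.asarray(orientation_id, dtype=int), (n,)).copy()
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = (self.b > 0) & (np.abs(norms - 1) > 1e-6)
        if np.any(bad):
            raise ValueError("non-unit gradient directions for b > 0 volumes")
        if np.any((self.b > 0) & (norms < 1e-12)):
            raise ValueError("zero gradient vector with b > 0")

    def __len__(self) -> int:
        return self.b.size

    @property
    def n_volumes(self) -> int:
        """Number of readout volumes (two per excitation)."""
        return 2 * len(self)

    @property
    def tphase_values(self) -> np.ndarray:
        """Sorted distinct phase-accumulation times (ms)."""
        return np.unique(self.t_phase)

    def volumes(self) -> Iterator[AcquisitionVolume]:
        """Expand into per-readout volumes, SE then ASE per excitation."""
        for readout in ("SE", "ASE"):
            for i in range(len(self)):
                yield AcquisitionVolume(
                    b=float(self.b[i]), g_hat=self.bvecs[i],
                    t_phase=float(self.t_phase[i]), readout=readout,
                    TE1=self.TE1, TE2=self.TE2, B0_hat=self.B0_hat[i],
                    orientation_id=int(self.orientation_id[i]),
                )

    def to_table(self) -> pd.DataFrame:
        """Per-volume acquisition table (one row per readout volume)."""
        rows = []
        for idx, v in enumerate(self.volumes()):
            rows.append(dict(
                index=idx, b=v.b, gx=v.g_hat[0], gy=v.g_hat[1],
                gz=v.g_hat[2], t_phase=v.t_phase, readout=v.readout,
                orientation=v.orientation_id,
            ))
        return pd.DataFrame(rows)

    def with_B0(self, B0_hat, orientation_id: int) -> "Scheme":
        """Copy of this scheme under a different head orientation."""
        return Scheme(self.b, self.bvecs, self.t_phase, self.TE1, self.TE2,
                      B0_hat=np.asarray(B0_hat, float),
                      orientation_id=orientation_id)

    @staticmethod
    def concatenate(schemes) -> "Scheme":
        schemes = list(schemes)
        te1 = {s.TE1 for s in schemes}
        te2 = {s.TE2 for s in schemes}
        if len(te1) != 1 or len(te2) != 1:
            raise ValueError("cannot concatenate schemes with different echo times")
        return Scheme(
            np.concatenate([s.b for s in schemes]),
            np.concatenate([s.bvecs for s in schemes]),
            np.concatenate([s.t_phase for s in schemes]),
            te1.pop(), te2.pop(),
            B0_hat=np.concatenate([s.B0_hat for s in schemes]),
            orientation_id=np.concatenate([s.orientation_id for s in schemes]),
        )

    @classmethod
    def dippi_shell(cls, n_directions: int = 60, b: float = 3.0,
                    t_phases=(30.0,), n_b0: int = 0, TE1: float = 50.0,
                    TE2: float = 70.0, B0_hat=None,
                    reverse: bool = True) -> "Scheme":
        """Single-shell DIPPI scheme: ``n_directions`` evenly spread
        gradients — acquired together with their reversed polarities by
        default, as antipodal pairs are what separate the odd (eddy) from
        the even (susceptibility) phase — repeated at each t_phase, plus
        optional b=0 excitations (acquired once, at the first t_phase)."""
        dirs = fibonacci_directions(n_directions)
        if reverse:
            dirs = np.vstack([dirs, -dirs])
            n_directions = 2 * n_directions
        bs, gs, ts = [], [], []
        if n_b0:
            bs.append(np.zeros(n_b0))
            gs.append(np.zeros((n_b0, 3)))
            ts.append(np.full(n_b0, t_phases[0]))
        for t in t_phases:
            bs.append(np.full(n_directions, b))
            gs.append(dirs)
            ts.append(np.full(n_directions, t))
        return cls(np.concatenate(bs), np.concatenate(gs), np.concatenate(ts),
                   TE1, TE2, B0_hat=B0_hat)


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly evenly spread unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
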