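"""Sensor-net geometry.

A :class:`Montage` holds unit-sphere electrode positions (scalp radius
normalized to 1) plus an angular-distance adjacency.  The generator lays
channels quasi-uniformly on the upper hemisphere with a Fibonacci spiral,
standing in for a high-density geodesic net.  The outermost belt of a
128-channel layout — the channels most exposed to muscle artifact — can be
dropped to obtain the 110-channel analysis montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Indices of the outermost belt of the packaged 128-channel layout.  By
#: construction of the Fibonacci spiral the last 18 indices are the lowest
#: channels on the head; removing them leaves the 110-channel analysis set.
OUTER_BELT_128 = list(range(110, 128))

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class Montage:
    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm
    adjacency: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidArgumentError("positions must be (n_channels, 3)")
        if len(self.labels) != len(self.positions):
            raise InvalidArgumentError("labels and positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("channel labels must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidArgumentError("positions must lie on the unit sphere")
        for i, nbrs in self.adjacency.items():
            for j in nbrs:
                if i not in self.adjacency.get(j, []):
                    raise InvalidArgumentError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def drop(self, indices) -> "Montage":
        """Return a montage without the given channel indices (adjacency rebuilt)."""
        keep = [i for i in range(self.n_channels) if i not in set(indices)]
        labels = [self.labels[i] for i in keep]
        pos = self.positions[keep]
        return Montage(labels, pos, _angular_adjacency(pos))


def _angular_adjacency(positions: np.ndarray, factor: float = 1.6) -> dict[int, list[int]]:
    """Neighbors within ``factor`` x the median nearest-neighbor angle."""
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    np.fill_diagonal(ang, np.inf)
    nn = np.min(ang, axis=1)
    thresh = factor * float(np.median(nn))
    adj: dict[int, list[int]] = {}
    for i in range(len(positions)):
        adj[i] = sorted(np.nonzero(ang[i] <= thresh)[0].tolist())
    return adj


def gen_montage(n_channels: int, seed: int = 0, z_min: float = -0.2) -> Montage:
    """Quasi-uniform upper-hemisphere montage via a Fibonacci spiral.

    Channels are ordered from vertex downward, so the trailing indices form
    the outermost belt.  ``seed`` rotates the spiral's azimuthal phase;
    output is deterministic for a fixed seed.
    """
    if n_channels < 4:
        raise InvalidArgumentError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_channels)
    z = 1.0 - (i + 0.5) * (1.0 - z_min) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * _GOLDEN_ANGLE + phase
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = [f"E{k + 1}" for k in range(n_channels)]
    return Montage(labels, pos, _angular_adjacency(pos))


def standard_montage_110(seed: int = 7) -> Montage:
    """The packaged 128-channel layout reduced to its 110 analysis channels."""
    return gen_montage(128, seed=seed).drop(OUTER_BELT_128)


def write_sfp(path, montage: Montage) -> None:
    """Write electrode positions as .sfp-style text (label x y z)."""
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")


def read_sfp(path) -> Montage:
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                from .errors import FormatError

                raise FormatError(f"bad .sfp line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    pos = np.asarray(rows)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels, pos, _angular_adjacency(pos))
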