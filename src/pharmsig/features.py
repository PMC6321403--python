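"""Pharmacophore feature points and point-set pharmacophores.

A pharmacophore is modelled as a complete graph: vertices are labelled
3D feature points (H-bond acceptor/donor, aromatic, hydrophobic,
positive/negative centre), edges carry the Euclidean distance between
features, discretised into bins of a fixed step so that matching is
tolerant of small geometric variation.

Two features may legitimately share identical coordinates: a single
fragment (e.g. an aromatic ring) can carry several feature types at
once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Default feature-type alphabet: acceptor, donor, aromatic, hydrophobic,
#: positive centre, negative centre.  Extensible — any short string label
#: free of the characters ``| ; : / # *`` (reserved by the signature
#: serialisation) is accepted.
DEFAULT_ALPHABET = ("A", "D", "a", "H", "P", "N")

_RESERVED = set("|;:/#*\n\t ")


@dataclass(frozen=True, order=True)
class FeaturePoint:
    """A single pharmacophore feature: a type label at a 3D position (Å)."""

    label: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not self.label or _RESERVED & set(self.label):
            raise ValueError(f"invalid feature label {self.label!r}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("feature coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class Pharmacophore:
    """An ordered collection of :class:`FeaturePoint` with a distance bin step.

    Parameters
    ----------
    features
        Iterable of :class:`FeaturePoint` (or ``(label, x, y, z)`` tuples).
    bin_step
        Width in Å of the half-open distance bins ``[k*step, (k+1)*step)``
        used for all graph signatures; must be positive. Default 1.0 Å.
    """

    __slots__ = ("_features", "_bin_step", "_coords")

    def __init__(self, features: Iterable = (), bin_step: float = 1.0):
        if not bin_step > 0:
            raise ValueError("bin_step must be positive")
        feats = []
        for f in features:
            if not isinstance(f, FeaturePoint):
                f = FeaturePoint(str(f[0]), float(f[1]), float(f[2]), float(f[3]))
            feats.append(f)
        self._features: tuple[FeaturePoint, ...] = tuple(feats)
        self._bin_step = float(bin_step)
        self._coords: np.ndarray | None = None

    @property
    def features(self) -> tuple[FeaturePoint, ...]:
        return self._features

    @property
    def bin_step(self) -> float:
        return self._bin_step

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self._features)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        if self._coords is None:
            if self._features:
                self._coords = np.array(
                    [[f.x, f.y, f.z] for f in self._features], dtype=float
                )
            else:
                self._coords = np.empty((0, 3), dtype=float)
        return self._coords

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features)

    def __getitem__(self, i: int) -> FeaturePoint:
        return self._features[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pharmacophore):
            return NotImplemented
        return (
            self._features == other._features and self._bin_step == other._bin_step
        )

    def __hash__(self):
        return hash((self._features, self._bin_step))

    def __repr__(self) -> str:
        return f"Pharmacophore({len(self)} features, bin_step={self._bin_step})"

    def subset(self, indices: Sequence[int]) -> "Pharmacophore":
        """Sub-pharmacophore induced by ``indices`` (same bin step)."""
        return Pharmacophore(
            (self._features[i] for i in indices), bin_step=self._bin_step
        )

    def distance_matrix(self) -> np.ndarray:
        """Dense pairwise Euclidean distance matrix (Å)."""
        c = self.coords
        d = c[:, None, :] - c[None, :, :]
        return np.sqrt((d * d).sum(axis=2))

    # ---------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        return {
            "bin_step": self._bin_step,
            "features": [
                {"label": f.label, "x": f.x, "y": f.y, "z": f.z}
                for f in self._features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pharmacophore":
        return cls(
            (
                FeaturePoint(f["label"], float(f["x"]), float(f["y"]), float(f["z"]))
                for f in d["features"]
            ),
            bin_step=float(d.get("bin_step", 1.0)),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "Pharmacophore":
        """Read from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def to_xyz(self, path=None) -> str:
        """Plain-text dialect: one ``label x y z`` line per feature.

        A ``# bin_step <value>`` comment line records the bin step.
        """
        lines = [f"# bin_step {self._bin_step!r}"]
        lines += [f"{f.label} {f.x!r} {f.y!r} {f.z!r}" for f in self._features]
        s = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_xyz(cls, source) -> "Pharmacophore":
        """Read the ``label x y z`` dialect from a string or file path."""
        text = str(source)
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
        bin_step = 1.0
        feats = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "bin_step":
                    bin_step = float(parts[1])
                continue
            label, x, y, z = line.split()
            feats.append(FeaturePoint(label, float(x), float(y), float(z)))
        return cls(feats, bin_step=bin_step)
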