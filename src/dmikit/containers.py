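"""In-memory and on-disk containers exchanged between pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acquisition import AcquisitionParams


@dataclass
class SpectralGrid:
    """A 4D complex CSI dataset: free induction decays over (x, y, z, t).

    The spectral (time) axis is last.  ``acq`` carries the axes metadata
    (dwell time, bandwidth, Larmor frequency) needed to reconstruct spectra.
    """

    data: np.ndarray  # complex, shape (nx, ny, nz, n_spectral)
    acq: AcquisitionParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"SpectralGrid expects 4D data, got {self.data.ndim}D")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.data.shape[-1] != self.acq.n_spectral:
            raise ValueError(
                f"spectral axis length {self.data.shape[-1]} != "
                f"acquisition n_spectral {self.acq.n_spectral}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy(self) -> "SpectralGrid":
        return SpectralGrid(self.data.copy(), self.acq, dict(self.meta))

    # -- persistence: platform-neutral .npy array + JSON sidecar ------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` (complex array) and ``<path>.json`` sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {
            "acquisition": self.acq.model_dump(),
            "axes": ["x", "y", "z", "time"],
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpectralGrid":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        acq = AcquisitionParams(**sidecar["acquisition"])
        return cls(data, acq, sidecar.get("meta", {}))
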