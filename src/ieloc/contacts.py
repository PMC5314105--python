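"""Electrode/contact records shared by the ECoG and SEEG pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Contact:
    """One recording site.

    ``position`` is native world mm; ``mni`` is filled by the standard-space
    transform; ``labels`` holds one LabelResult per atlas consulted.
    """

    electrode: str
    index: int                       # 1-based within the electrode
    position: np.ndarray
    padded: bool = False
    mni: np.ndarray | None = None
    mni_out_of_field: bool = False
    labels: list = field(default_factory=list)

    @property
    def id(self) -> str:
        return f"{self.electrode}{self.index}"


@dataclass
class ElectrodeSet:
    """Named electrodes with ordered contacts plus an edit audit log."""

    contacts: list[Contact] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None
    audit_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def electrode_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.contacts:
            seen.setdefault(c.electrode, None)
        return list(seen)

    def positions(self) -> np.ndarray:
        if not self.contacts:
            return np.zeros((0, 3))
        return np.vstack([c.position for c in self.contacts])

    def by_electrode(self, name: str) -> list[Contact]:
        return [c for c in self.contacts if c.electrode == name]

    def get(self, contact_id: str) -> Contact:
        for c in self.contacts:
            if c.id == contact_id:
                return c
        raise KeyError(f"no contact with id {contact_id!r}")

    def copy(self) -> "ElectrodeSet":
        return ElectrodeSet(
            contacts=[Contact(c.electrode, c.index, np.array(c.position, float),
                              c.padded,
                              None if c.mni is None else np.array(c.mni, float),
                              c.mni_out_of_field, list(c.labels))
                      for c in self.contacts],
            grid_shape=self.grid_shape,
            audit_log=list(self.audit_log),
        )


def from_points(points: np.ndarray, electrode: str = "G",
                grid_shape: tuple[int, int] | None = None) -> ElectrodeSet:
    """Wrap an (n, 3) array of world-mm points as a single named electrode."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return ElectrodeSet(
        contacts=[Contact(electrode, i + 1, p.copy()) for i, p in enumerate(pts)],
        grid_shape=grid_shape,
    )
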