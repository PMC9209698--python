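"""In-memory training-set container shared by the phantom generator and trainers."""

from __future__ import annotations

from dataclasses import dataclass

from .volume_io import BinaryMask, Volume3D

__all__ = ["TrainingSet"]


@dataclass
class TrainingSet:
    """A list of (volume, mask, subject_id) triples.

    Several scans may share a subject id (repeat fetal scans); cross-validation
    splits must keep all scans of a subject in the same fold.
    """

    items: list[tuple[Volume3D, BinaryMask, str]]

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("TrainingSet requires at least one item")
        for vol, mask, sid in self.items:
            if vol.shape != mask.shape:
                raise ValueError(
                    f"volume/mask shape mismatch for subject {sid}: "
                    f"{vol.shape} vs {mask.shape}"
                )

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def subject_ids(self) -> list[str]:
        return [sid for _, _, sid in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> tuple[Volume3D, BinaryMask, str]:
        return self.items[i]

    def subset(self, indices) -> "TrainingSet":
        return TrainingSet([self.items[i] for i in indices])
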