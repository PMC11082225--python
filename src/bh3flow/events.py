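"""Core containers: event tables, tube records, and the tube manifest.

An :class:`EventTable` is the in-memory form of one cytometer tube — an
events × channels matrix of non-negative intensities, optionally carrying
per-event ground-truth labels when the tube was simulated.  A
:class:`Manifest` maps tube files on disk to their experimental condition
(sample, reagent, concentration, replicate, control role).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: canonical channel order used by the simulator and default configs
DEFAULT_CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "Zombie", "CD5", "CD19", "CytC")

#: recognised control roles in a manifest
CONTROL_ROLES = ("none", "PUMA2A", "alamethicin", "DMSO")


class ValidationError(ValueError):
    """Raised when a container or preset violates one of its invariants."""


@dataclass
class EventTable:
    """Events × channels matrix for a single tube.

    Parameters
    ----------
    channels
        Ordered channel names, one per column of ``values``.
    values
        Array of shape ``(n_events, n_channels)``; finite and >= 0.
    truth_labels
        Optional DataFrame with one row per event and columns
        ``population`` (debris/doublet/dead/non_target/target) and
        ``released`` (bool); present only for simulated tubes.
    """

    channels: Sequence[str]
    values: np.ndarray
    truth_labels: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("event intensities must be finite")
        if np.any(self.values < 0):
            raise ValidationError("event intensities must be non-negative")
        if self.truth_labels is not None and len(self.truth_labels) != len(self):
            raise ValidationError(
                "truth_labels must have exactly one entry per event"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the intensity column for ``name``."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in {self.channels}")
        return self.values[:, idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row-subset preserving truth labels."""
        mask = np.asarray(mask)
        truth = None
        if self.truth_labels is not None:
            truth = self.truth_labels.iloc[np.flatnonzero(mask)].reset_index(drop=True) \
                if mask.dtype == bool else self.truth_labels.iloc[mask].reset_index(drop=True)
        return EventTable(self.channels, self.values[mask], truth)

    def to_dataframe(self, include_truth: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channels))
        if include_truth and self.truth_labels is not None:
            df["population"] = self.truth_labels["population"].to_numpy()
            df["released"] = self.truth_labels["released"].astype(int).to_numpy()
        return df


@dataclass(frozen=True)
class TubeRecord:
    """One manifest row: where a tube lives and what condition it carries."""

    path: str
    sample_id: str
    reagent: str
    concentration_uM: float
    replicate: int
    control_role: str = "none"

    def __post_init__(self) -> None:
        if self.control_role not in CONTROL_ROLES:
            raise ValidationError(
                f"control_role {self.control_role!r} not one of {CONTROL_ROLES}"
            )

    @property
    def condition(self) -> tuple:
        return (self.reagent, self.concentration_uM)


MANIFEST_COLUMNS = (
    "file", "sample_id", "reagent", "concentration_uM", "replicate", "control_role",
)


@dataclass
class Manifest:
    """Collection of tube records with per-sample control invariants.

    Every sample must carry exactly one PUMA2A (full cyt c retention) and one
    alamethicin (complete release) control condition — each possibly in
    replicate — and replicate indices within a condition must be unique.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = list(self.records)
        self.validate()

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.sample_id, rec.reagent, rec.concentration_uM,
                   rec.control_role, rec.replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate replicate index {rec.replicate} for sample "
                    f"{rec.sample_id!r} condition ({rec.reagent}, {rec.concentration_uM})"
                )
            seen.add(key)
        for sample in self.sample_ids():
            roles = {r.control_role for r in self.records if r.sample_id == sample}
            for needed in ("PUMA2A", "alamethicin"):
                if needed not in roles:
                    raise ValidationError(
                        f"sample {sample!r} lacks a {needed} control tube"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sample_ids(self) -> list:
        out = []
        for rec in self.records:
            if rec.sample_id not in out:
                out.append(rec.sample_id)
        return out

    def for_sample(self, sample_id: str) -> list:
        return [r for r in self.records if r.sample_id == sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.path, r.sample_id, r.reagent, r.concentration_uM,
              r.replicate, r.control_role) for r in self.records],
            columns=list(MANIFEST_COLUMNS),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Manifest":
        df = pd.read_csv(path, sep="\t")
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        recs = [
            TubeRecord(
                path=str(row.file),
                sample_id=str(row.sample_id),
                reagent=str(row.reagent),
                concentration_uM=float(row.concentration_uM),
                replicate=int(row.replicate),
                control_role=str(row.control_role),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs)
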