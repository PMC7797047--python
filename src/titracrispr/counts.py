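"""Dense (guide x barcode x timepoint) read-count tensor with TSV round trip."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountTensor", "read_count_table", "write_count_table"]


@dataclass
class CountTensor:
    """Integer read counts indexed by (guide, barcode, timepoint).

    ``hours`` is the sampling schedule of the pooled selection; it must be
    strictly increasing and start at 0 (the pre-selection reference point).
    """

    guides: list[str]
    barcodes: list[str]
    hours: np.ndarray
    counts: np.ndarray  # shape (n_guides, n_barcodes, n_timepoints)
    environment: str = ""

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guides), len(self.barcodes), len(self.hours)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.guides)}, {len(self.barcodes)}, {len(self.hours)})"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if len(self.hours) and (np.any(np.diff(self.hours) <= 0) or self.hours[0] != 0):
            raise ValueError("schedule must be strictly increasing and start at 0")
        self._guide_idx = {g: i for i, g in enumerate(self.guides)}
        self._barcode_idx = {b: i for i, b in enumerate(self.barcodes)}
        if len(self._guide_idx) != len(self.guides):
            raise ValueError("duplicate guide ids")

    # -- access -----------------------------------------------------------
    def guide(self, guide_id: str) -> np.ndarray:
        """Counts for one guide, shape (n_barcodes, n_timepoints)."""
        return self.counts[self._guide_idx[guide_id]]

    def pooled(self) -> np.ndarray:
        """Counts summed over barcodes, shape (n_guides, n_timepoints)."""
        return self.counts.sum(axis=1)

    def totals(self) -> np.ndarray:
        """Total reads per timepoint."""
        return self.counts.sum(axis=(0, 1))

    # -- IO ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        g, b, t = np.meshgrid(
            np.arange(len(self.guides)),
            np.arange(len(self.barcodes)),
            np.arange(len(self.hours)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "guide_id": np.asarray(self.guides, dtype=object)[g.ravel()],
                "barcode": np.asarray(self.barcodes, dtype=object)[b.ravel()],
                "hour": self.hours[t.ravel()],
                "count": self.counts.ravel(),
            }
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame().sort_values(["guide_id", "barcode", "hour"], kind="stable")
        df.to_csv(path, sep="\t", index=False)


def write_count_table(ct: CountTensor, path) -> None:
    ct.write_tsv(path)


def read_count_table(path, environment: str = "", schedule_hours=None) -> CountTensor:
    """Read a count TSV back into a dense tensor.

    Missing (guide, barcode, hour) combinations are filled with 0 (with a
    warning); duplicate rows, negative counts and a ``schedule_hours`` that
    is non-monotone or inconsistent with the file are errors.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"guide_id", "barcode", "hour", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    if df.duplicated(["guide_id", "barcode", "hour"]).any():
        raise ValueError("duplicate (guide, barcode, hour) rows")
    if (df["count"] < 0).any():
        raise ValueError("negative counts")
    hours = np.sort(df["hour"].unique().astype(float))
    if schedule_hours is not None:
        schedule_hours = np.asarray(schedule_hours, dtype=float)
        if np.any(np.diff(schedule_hours) <= 0):
            raise ValueError("schedule_hours must be strictly increasing")
        if not set(hours).issubset(set(schedule_hours)):
            raise ValueError("file contains hours outside schedule_hours")
        hours = schedule_hours
    guides = sorted(df["guide_id"].unique())
    barcodes = sorted(df["barcode"].unique())
    full = len(guides) * len(barcodes) * len(hours)
    if len(df) < full:
        warnings.warn(
            f"count table is sparse ({len(df)}/{full} rows); missing combinations read as 0",
            stacklevel=2,
        )
    gi = {g: i for i, g in enumerate(guides)}
    bi = {b: i for i, b in enumerate(barcodes)}
    ti = {h: i for i, h in enumerate(hours)}
    counts = np.zeros((len(guides), len(barcodes), len(hours)), dtype=np.int64)
    counts[
        df["guide_id"].map(gi).to_numpy(),
        df["barcode"].map(bi).to_numpy(),
        df["hour"].astype(float).map(ti).to_numpy(),
    ] = df["count"].to_numpy()
    return CountTensor(guides, barcodes, hours, counts, environment=environment)
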