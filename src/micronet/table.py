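"""Validated sample-by-taxon count table with aligned sample metadata.

The :class:`AbundanceTable` is the universal input of the pipeline: a matrix
of non-negative integer read counts whose rows are samples (e.g. individual
whale-shark epidermal metagenomes) and whose columns are taxa (family-level
labels), plus optional per-sample categorical factors such as the aggregation
a shark was sampled at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable"]


class TableValidationError(ValueError):
    """Raised when a count table violates the container invariants."""


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with aligned categorical metadata.

    Parameters
    ----------
    counts:
        DataFrame of non-negative integer counts; index = sample ids,
        columns = taxon ids, both unique.
    metadata:
        Optional DataFrame of per-sample factors (strings), indexed by
        sample id and aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = pd.DataFrame(self.counts)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise TableValidationError(f"duplicate identifier: sample {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise TableValidationError(f"duplicate identifier: taxon {dup!r}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            bad = np.zeros(arr.shape, dtype=bool)
            coerced = np.empty(arr.shape, dtype=float)
            for idx, val in np.ndenumerate(arr):
                try:
                    coerced[idx] = float(val)
                except (TypeError, ValueError):
                    bad[idx] = True
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise TableValidationError(
                    "malformed count: non-numeric value "
                    f"{arr[i, j]!r} at sample {counts.index[i]!r}, "
                    f"taxon {counts.columns[j]!r}"
                )
            arr = coerced
        arr = np.asarray(arr, dtype=float)
        if np.isnan(arr).any() or (arr < 0).any():
            mask = np.isnan(arr) | (arr < 0)
            i, j = np.argwhere(mask)[0]
            raise TableValidationError(
                "malformed count: negative or missing value "
                f"{arr[i, j]} at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            mask = ~np.isclose(arr, np.round(arr))
            i, j = np.argwhere(mask)[0]
            raise TableValidationError(
                "malformed count: non-integral value "
                f"{arr[i, j]} at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        self.counts = pd.DataFrame(
            arr.astype(np.int64), index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.index)
        else:
            meta = pd.DataFrame(self.metadata)
            meta.index = meta.index.astype(str)
            missing = self.counts.index.difference(meta.index)
            if len(missing):
                raise TableValidationError(
                    f"metadata missing sample {missing[0]!r}"
                )
            self.metadata = meta.loc[self.counts.index].astype(str)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        """Counts as an int64 array (samples x taxa)."""
        return self.counts.to_numpy()

    def select_samples(self, sample_ids) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(self.counts.loc[ids], self.metadata.loc[ids])

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[:, list(taxon_ids)], self.metadata)

    def groups(self, factor: str) -> pd.Series:
        """Per-sample factor levels in table order."""
        if factor not in self.metadata.columns:
            raise KeyError(f"metadata has no factor {factor!r}")
        return self.metadata[factor]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.equals(
            other.metadata
        )
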