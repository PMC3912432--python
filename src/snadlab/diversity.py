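"""Diversity statistics for marker-gene clone libraries.

Clone libraries are small (typically 6-12 clones per marker gene), so
the statistics kept here are the ones meaningful at that depth: the
Shannon index H in nats and its evenness normalizations.  Because with
n clones the index is bounded both by ln S (S observed taxa) and by
ln n, both normalizations are computed; which one a published value
used is often ambiguous, so reports carry both rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["CloneCounts", "shannon", "evenness", "read_clone_counts"]


@dataclass(frozen=True)
class CloneCounts:
    """Taxon -> clone-count table for one marker-gene library."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    marker: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise DomainError("labels and counts must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("labels must be unique")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise DomainError("counts must be non-negative integers")
        if sum(self.counts) <= 0:
            raise DomainError("at least one count must be positive")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_clones(self) -> int:
        return sum(self.counts)

    @property
    def richness(self) -> int:
        """Number of taxa with at least one clone."""
        return sum(1 for c in self.counts if c > 0)

    def summary(self) -> dict:
        H = shannon(self.counts)
        e_richness, e_sample, flag = evenness(self.counts, self.n_clones)
        return {
            "marker": self.marker,
            "n_clones": self.n_clones,
            "richness": self.richness,
            "shannon_H_nats": H,
            "evenness_by_richness": e_richness,
            "evenness_by_sample_size": e_sample,
            "single_class": flag,
        }


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats.

    Zero-count classes are ignored; an all-zero table is a domain error.

    Examples
    --------
    >>> round(shannon([6, 1, 1]), 4)
    0.7356
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise DomainError("counts must be >= 0")
    total = c.sum()
    if total <= 0:
        raise DomainError("all counts are zero")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def evenness(counts, n: int | None = None) -> tuple[float, float, bool]:
    """Shannon evenness under both normalizations.

    Returns ``(E_richness, E_sample, single_class)`` where
    ``E_richness = H / ln S`` (S = observed taxa) and
    ``E_sample = H / ln n`` (n = total clones, override with ``n``).
    With a single observed class both evennesses are defined as 0 and
    the flag is set.

    Examples
    --------
    >>> e_s, e_n, flag = evenness([6, 1, 1])
    >>> round(e_n, 4), flag
    (0.3538, False)
    """
    c = np.asarray(counts, dtype=float)
    H = shannon(c)
    S = int((c > 0).sum())
    total = int(c.sum()) if n is None else int(n)
    if S < 2:
        return 0.0, 0.0, True
    e_richness = H / np.log(S)
    e_sample = H / np.log(total) if total > 1 else 0.0
    return float(e_richness), float(e_sample), False


def read_clone_counts(path, marker: str = "") -> CloneCounts:
    """Read a ``label,count`` CSV into a :class:`CloneCounts` table."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "label" not in cols or "count" not in cols:
        raise DomainError("clone-count CSV must have 'label' and 'count' columns")
    return CloneCounts(
        labels=tuple(str(x) for x in df[cols["label"]]),
        counts=tuple(int(x) for x in df[cols["count"]]),
        marker=marker,
    )
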