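"""Core data model for the diallel-cross MethylRAD pipeline.

The pipeline's root input is a table of read counts at methylation-dependent
restriction sites (CCGG and CCWGG, W = A or T): read depth at a site is the
methylation signal.  All coordinates are 1-based inclusive internally; BED
input/output is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLOWED_CONTEXTS = ("CCGG", "CCWGG")

#: Genomic element labels, in primary-assignment priority order (gene-centric
#: first).  exon/intron are memberships only, never a primary label.
ELEMENT_PRIORITY = ("gene_body", "upstream2k", "downstream2k", "TE", "intergenic")
ELEMENT_LABELS = ("gene_body", "exon", "intron", "upstream2k", "downstream2k", "TE", "intergenic")

#: The six non-additive inheritance patterns plus the additive default.
PATTERN_LABELS = ("Additive", "HP", "LP", "GT_HP", "LT_LP", "Above", "Below")
PARENTAL_CATEGORIES = ("A_gt_B", "B_gt_A", "equal_pos", "equal_zero")


@dataclass(frozen=True)
class MethylSite:
    """A single CCGG/CCWGG restriction site (unstranded)."""

    chrom: str
    pos: int  # 1-based position of the site's first base
    context: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.context not in ALLOWED_CONTEXTS:
            raise ValueError(
                f"context must be one of {ALLOWED_CONTEXTS}, got {self.context!r}"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A gene model (1-based inclusive span, stranded)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class TeFeature:
    """A transposable-element interval (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    te_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"TE {self.te_id}: start {self.start} > end {self.end}")


class SiteCountTable:
    """Per-site raw counts across all samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos``, ``context`` (one row per
        site, unique on the triple).
    counts
        Non-negative integer matrix, sites x samples.
    samples
        Ordered sample names (columns of ``counts``).
    library_sizes
        Per-sample sequencing depth used for RPM normalisation; defaults to
        the column sums of ``counts``.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        counts: np.ndarray,
        samples: list[str],
        library_sizes: np.ndarray | None = None,
    ) -> None:
        sites = sites.reset_index(drop=True)
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape != (len(sites), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        bad = ~sites["context"].isin(ALLOWED_CONTEXTS)
        if bad.any():
            raise ValueError(
                f"unknown context value(s): {sorted(sites.loc[bad, 'context'].unique())}"
            )
        if sites.duplicated(["chrom", "pos", "context"]).any():
            dup = sites[sites.duplicated(["chrom", "pos", "context"], keep=False)]
            raise ValueError(f"duplicate (chrom, pos, context) rows: {len(dup)} involved")
        if (sites["pos"] < 1).any():
            raise ValueError("site positions must be >= 1")
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        library_sizes = np.asarray(library_sizes, dtype=np.int64)
        if library_sizes.shape != (len(samples),):
            raise ValueError("library_sizes length must equal the number of samples")
        if (library_sizes <= 0).any():
            raise ValueError("library_sizes must be positive")
        self.sites = sites
        self.counts = counts.astype(np.int64)
        self.samples = list(samples)
        self.library_sizes = library_sizes

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in count table") from None

    def column(self, name: str) -> np.ndarray:
        return self.counts[:, self.sample_index(name)]

    def library_size(self, name: str) -> int:
        return int(self.library_sizes[self.sample_index(name)])

    def context_mask(self, context: str) -> np.ndarray:
        return (self.sites["context"] == context).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Site metadata and counts as a single DataFrame (write format)."""
        out = self.sites.copy()
        for j, s in enumerate(self.samples):
            out[s] = self.counts[:, j]
        return out


@dataclass
class CrossDesign:
    """Roles of samples in a diallel cross.

    ``parents`` maps parent codes (P1, P2, P3, ...) to sample names;
    ``hybrids`` lists (hybrid sample name, maternal code, paternal code);
    ``combinations`` lists (name, hybrid A, hybrid B) where A and B are
    reciprocal crosses of the same parent pair.
    """

    parents: dict[str, str]
    hybrids: list[tuple[str, str, str]]
    combinations: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        hyb = {name: (m, p) for name, m, p in self.hybrids}
        for name, m, p in self.hybrids:
            if m == p:
                raise ValueError(f"hybrid {name}: maternal == paternal parent {m}")
            for code in (m, p):
                if code not in self.parents:
                    raise ValueError(f"hybrid {name}: unknown parent code {code}")
        for name, a, b in self.combinations:
            for h in (a, b):
                if h not in hyb:
                    raise ValueError(f"combination {name}: unknown hybrid {h}")
            if hyb[a] != hyb[b][::-1]:
                raise ValueError(
                    f"combination {name}: {a} and {b} are not reciprocal crosses"
                )

    def hybrid_parents(self, hybrid: str) -> tuple[str, str]:
        """(maternal sample, paternal sample) for a hybrid."""
        for name, m, p in self.hybrids:
            if name == hybrid:
                return self.parents[m], self.parents[p]
        raise KeyError(f"unknown hybrid {hybrid!r}")

    def all_samples(self) -> list[str]:
        return list(self.parents.values()) + [h for h, _, _ in self.hybrids]

    def validate_against(self, table: SiteCountTable) -> None:
        missing = [s for s in self.all_samples() if s not in table.samples]
        if missing:
            raise ValueError(f"design references samples absent from counts: {missing}")


def default_diallel_design() -> CrossDesign:
    """The 3-parent full diallel used throughout: 3 parents, 6 reciprocal
    hybrids in 3 combinations (Fab has parent a as maternal line)."""
    return CrossDesign(
        parents={"P1": "P1", "P2": "P2", "P3": "P3"},
        hybrids=[
            ("F12", "P1", "P2"),
            ("F21", "P2", "P1"),
            ("F13", "P1", "P3"),
            ("F31", "P3", "P1"),
            ("F23", "P2", "P3"),
            ("F32", "P3", "P2"),
        ],
        combinations=[
            ("F1221", "F12", "F21"),
            ("F1331", "F13", "F31"),
            ("F2332", "F23", "F32"),
        ],
    )


@dataclass(frozen=True)
class Thresholds:
    """Significance and window thresholds, with the study defaults."""

    log2fc: float = 1.0
    p_value: float = 0.05
    hyper_multiple: float = 5.0
    flank: int = 2000
    min_term_genes: int = 5

    def __post_init__(self) -> None:
        if self.log2fc < 0 or self.p_value <= 0 or self.hyper_multiple <= 0:
            raise ValueError("thresholds must be positive")
        if self.flank < 0 or self.min_term_genes < 0:
            raise ValueError("thresholds must be positive")
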