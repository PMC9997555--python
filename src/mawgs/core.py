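"""Shared domain types for mutation-accumulation (MA) analyses.

An MA experiment propagates many replicate lines of a microbe through
repeated single-colony bottlenecks so that genetic drift dominates
selection; mutations therefore accumulate near-neutrally and their counts,
divided by the number of sites surveyed and cell divisions elapsed, give
an almost unbiased genome-wide mutation rate.  The types here are the
common currency of the whole package: a reference genome with gene
models, one called variant per line, per-line exposure bookkeeping, and
rate estimates with exact Poisson intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class MawgsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MawgsError):
    """Inconsistent experiment configuration (e.g. >2 lines per dish)."""


class DataIntegrityError(MawgsError):
    """Input data contradicts the reference (wrong genome build, etc.)."""


class AnnotationError(MawgsError):
    """Gene model cannot be annotated (e.g. internal stop codon)."""


class SizingError(MawgsError):
    """A synthetic genome specification does not fit its budgets."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered CDS intervals on one chromosome.

    Intervals are 1-based inclusive and stored in ascending genomic
    order; the coding strand is handled when the coding sequence is
    assembled.  Gaps between consecutive CDS intervals are introns.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    cds_intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = tuple(sorted((int(s), int(e)) for s, e in self.cds_intervals))
        for (s, e) in ivs:
            if s > e:
                raise ValueError(f"{self.gene_id}: empty CDS interval ({s}, {e})")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        object.__setattr__(self, "cds_intervals", ivs)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def intron_intervals(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.cds_intervals, self.cds_intervals[1:])
            if s2 > e1 + 1
        )

    @property
    def start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        return self.cds_intervals[-1][1]

    def coding_sequence(self, sequences: Dict[str, str]) -> str:
        """Concatenated CDS read 5'->3' on the coding strand."""
        chrom = sequences[self.chromosome]
        spliced = "".join(chrom[s - 1 : e] for s, e in self.cds_intervals)
        return spliced if self.strand == "+" else revcomp(spliced)


@dataclass(frozen=True)
class SSRTract:
    """A simple-sequence-repeat (microsatellite) tract.

    ``end - start + 1`` equals ``len(motif) * n_copies`` plus any partial
    tail; coordinates are 1-based inclusive.
    """

    chromosome: str
    start: int
    end: int
    motif: str
    n_copies: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceBundle:
    """Genome sequences plus gene models: the coordinate frame for all
    classification.  ``ssr_tracts`` carries planted-tract truth when the
    bundle comes from the simulator; real references leave it ``None``
    and tracts are detected from sequence."""

    sequences: Dict[str, str]
    genes: List[GeneModel]
    ssr_tracts: Optional[List[SSRTract]] = None

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: alphabet outside ACGTN: {sorted(bad)}")
        for g in self.genes:
            if g.chromosome not in self.sequences:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chromosome}")
            if g.end > len(self.sequences[g.chromosome]) or g.start < 1:
                raise ValueError(f"{g.gene_id}: outside chromosome bounds")

    @property
    def analyzable_sites(self) -> int:
        """Total non-N sites across the genome (the N of rate exposures)."""
        return sum(len(s) - s.count("N") for s in self.sequences.values())


@dataclass(frozen=True)
class MutationRecord:
    """One called variant in one MA line (VCF-style, 1-based, indels
    left-aligned with an anchor base)."""

    line_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        r, a = self.ref_allele, self.alt_allele
        if not r or not a:
            raise ValueError("empty allele")
        if len(r) == len(a) and len(r) > 1:
            raise ValueError(
                f"multi-nucleotide substitution {r}>{a} at "
                f"{self.chromosome}:{self.position} is not supported"
            )

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "BPS"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def site_key(self) -> Tuple[str, int, str, str]:
        """Identity used when checking for shared (contaminating) calls."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass
class LineMetadata:
    """Per-line exposure bookkeeping: divisions and analyzable sites
    drive rate denominators; depth and dish drive the QC filters."""

    line_id: str
    group: str  # 'control' or 'treatment'
    dish_id: str
    transfers: int
    divisions_per_transfer: int
    mean_depth: float
    analyzable_sites: int
    total_divisions: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_divisions is None:
            self.total_divisions = self.transfers * self.divisions_per_transfer
        if self.mean_depth < 0:
            raise ValueError(f"{self.line_id}: negative mean depth")

    @property
    def numeric_suffix(self) -> Optional[int]:
        """Trailing integer of the line id (used by the contamination rule)."""
        m = re.search(r"(\d+)$", self.line_id)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class MutationAnnotation:
    """A mutation together with every derived class used downstream."""

    record: MutationRecord
    region: str  # 'CDS' | 'intron' | 'intergenic'
    coding_effect: Optional[str]  # 'synonymous' | 'non-synonymous' | None
    at_fourfold_site: bool
    spectrum_class: Optional[str]  # one of six strand-collapsed classes
    ts_tv: Optional[str]  # 'transition' | 'transversion' | None
    context: Optional[str]  # 5' + focal + 3' on the reference strand
    in_ssr: Optional[bool]  # indels only
    gene_id: Optional[str] = None


@dataclass(frozen=True)
class RateEstimate:
    """A mutation count with its exposure and exact Poisson interval.

    ``exposure`` is summed (sites x divisions) over lines for per-site
    rates, or summed divisions for per-genome rates; ``rate`` and the
    interval bounds share exposure units.
    """

    m: int
    exposure: float
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("interval does not bracket the point estimate")
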