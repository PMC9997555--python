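"""Genome-wide denominators and per-mutation classification.

Two jobs live here.  First, the *site inventory*: how many analyzable
sites the genome offers in each category — region (CDS / intron /
intergenic), fractional synonymous and non-synonymous sites counted
Nei–Gojobori style (each coding position contributes k/3 synonymous
sites where k of the three alternative bases preserve the amino acid),
four-fold degenerate sites, and the 64 trinucleotide contexts.  These
counts are the denominators of every category-specific rate.  Second,
the classification of each called mutation: region, coding effect by
codon translation, strand-collapsed substitution class (six classes,
e.g. G:C→T:A), transition/transversion, reference-strand trinucleotide
context, and — for indels — overlap with simple-sequence-repeat (SSR)
tracts, the slippage hotspots where most spontaneous indels arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .core import (
    AnnotationError,
    DataIntegrityError,
    GeneModel,
    MutationAnnotation,
    MutationRecord,
    ReferenceBundle,
    SSRTract,
    revcomp,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Standard codon table with '*' for stops.
_table = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: Dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"

# Six strand-collapsed base-substitution classes: a change and its
# reverse-strand complement map to the same class.
SPECTRUM_CLASSES = (
    "A:T->G:C",
    "G:C->A:T",
    "A:T->T:A",
    "A:T->C:G",
    "G:C->C:G",
    "G:C->T:A",
)
TRANSITION_CLASSES = ("A:T->G:C", "G:C->A:T")
TRANSVERSION_CLASSES = ("A:T->T:A", "A:T->C:G", "G:C->C:G", "G:C->T:A")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_spectrum_map() -> Dict[Tuple[str, str], str]:
    pair_name = {
        ("A", "G"): "A:T->G:C",
        ("A", "T"): "A:T->T:A",
        ("A", "C"): "A:T->C:G",
        ("G", "A"): "G:C->A:T",
        ("G", "C"): "G:C->C:G",
        ("G", "T"): "G:C->T:A",
    }
    out: Dict[Tuple[str, str], str] = {}
    for (r, a), name in pair_name.items():
        out[(r, a)] = name
        out[(_COMP[r], _COMP[a])] = name
    return out


SPECTRUM_MAP = _build_spectrum_map()
_PURINES = {"A", "G"}


def spectrum_class_of(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution."""
    try:
        return SPECTRUM_MAP[(ref, alt)]
    except KeyError:
        raise ValueError(f"not a substitution: {ref}>{alt}") from None


def ts_tv_of(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or
    'transversion'."""
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return "transition" if (ref in _PURINES) == (alt in _PURINES) else "transversion"


def all_contexts() -> List[str]:
    """The 64 trinucleotide contexts in lexicographic order."""
    return [a + b + c for a in BASES for b in BASES for c in BASES]


def syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three alternative bases at codon position ``pos``
    (0-based) that leave the encoded amino acid (or stop) unchanged."""
    aa = CODON_AA[codon]
    n_syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if CODON_AA[alt] == aa:
            n_syn += 1
    return n_syn / 3.0


def is_fourfold(codon: str) -> bool:
    """True when all four bases at the third position encode the same
    amino acid."""
    return len({CODON_AA[codon[:2] + b] for b in BASES}) == 1


@dataclass
class SiteInventory:
    """Genome-wide denominators for rate estimation."""

    analyzable_sites_total: int
    sites_by_region: Dict[str, int]
    syn_sites: float
    nonsyn_sites: float
    fourfold_sites: int
    context_counts: Dict[str, int]

    def to_dict(self) -> dict:
        return {
            "analyzable_sites_total": self.analyzable_sites_total,
            "sites_by_region": dict(self.sites_by_region),
            "syn_sites": self.syn_sites,
            "nonsyn_sites": self.nonsyn_sites,
            "fourfold_sites": self.fourfold_sites,
            "context_counts": dict(self.context_counts),
        }


# region codes used in the per-position label arrays
_INTERGENIC, _INTRON, _CDS = 0, 1, 2
_REGION_NAME = {_INTERGENIC: "intergenic", _INTRON: "intron", _CDS: "CDS"}


def detect_ssrs(
    seq: str,
    min_copies: int = 3,
    min_tract_bp: int = 5,
    max_motif: int = 6,
    chromosome: str = "",
) -> List[SSRTract]:
    """Find maximal simple-sequence-repeat tracts in ``seq``.

    A tract is a maximal, non-extendable tandem run of a primitive motif
    of 1..``max_motif`` bp with at least ``min_copies`` full copies and
    at least ``min_tract_bp`` total length (partial trailing copies
    count toward length).  Overlapping candidate tracts with different
    motifs are resolved to the longest tract, ties to the shortest
    motif, then to the leftmost start.
    """
    if not 1 <= max_motif <= 6:
        raise ValueError("max_motif must be in 1..6")
    L = len(seq)
    cands: List[SSRTract] = []
    if L == 0:
        return cands
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for k in range(1, max_motif + 1):
        if L <= k:
            break
        match = arr[k:] == arr[:-k]  # match[i] True <=> seq[i+k] == seq[i]
        # maximal runs of True
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]  # index into `match`
        ends = np.nonzero(diff == -1)[0] - 1
        for s, e in zip(starts, ends):
            t_start, t_end = int(s), int(e) + k  # 0-based tract span
            length = t_end - t_start + 1
            copies = length // k
            if copies < min_copies or length < min_tract_bp:
                continue
            motif = seq[t_start : t_start + k]
            if "N" in motif or not _is_primitive(motif):
                continue
            cands.append(
                SSRTract(
                    chromosome=chromosome,
                    start=t_start + 1,
                    end=t_end + 1,
                    motif=motif,
                    n_copies=copies,
                )
            )
    return resolve_overlaps(cands)


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def resolve_overlaps(tracts: Sequence[SSRTract]) -> List[SSRTract]:
    """Greedy non-overlapping selection: longest tract first, ties to
    the shortest motif, then leftmost."""
    chosen: List[SSRTract] = []
    occupied: List[Tuple[int, int]] = []
    for t in sorted(tracts, key=lambda t: (-t.length, len(t.motif), t.start)):
        if any(t.start <= e and s <= t.end for s, e in occupied):
            continue
        chosen.append(t)
        occupied.append((t.start, t.end))
    return sorted(chosen, key=lambda t: (t.chromosome, t.start))


def indel_in_ssr(
    rec: MutationRecord, tracts: Sequence[SSRTract], flank_bp: int = 1
) -> bool:
    """True iff the indel's affected span, widened by ``flank_bp``,
    intersects any tract on the same chromosome.

    The affected span is the anchor base plus the following base for an
    insertion (the new bases land between them), or the deleted bases
    for a deletion.
    """
    if rec.kind == "BPS":
        raise ValueError("indel_in_ssr is defined for indels only")
    if rec.kind == "insertion":
        lo, hi = rec.position, rec.position + 1
    else:
        lo, hi = rec.position + 1, rec.position + len(rec.ref_allele) - 1
    lo -= flank_bp
    hi += flank_bp
    return any(
        t.chromosome == rec.chromosome and lo <= t.end and t.start <= hi
        for t in tracts
    )


class GenomeAnnotator:
    """Precomputed per-position indexes over a reference bundle.

    Builds region label arrays (CDS > intron > intergenic, with the
    longest transcript winning where gene models overlap), a per-position
    owning-gene index, codon lookups, and SSR tracts, then serves both
    the site inventory and per-record classification.
    """

    def __init__(
        self,
        ref: ReferenceBundle,
        ssr_min_copies: int = 3,
        ssr_min_tract_bp: int = 5,
        ssr_max_motif: int = 6,
        ssr_flank_bp: int = 1,
    ) -> None:
        self.ref = ref
        self.ssr_flank_bp = ssr_flank_bp
        self._labels: Dict[str, np.ndarray] = {}
        self._owner: Dict[str, np.ndarray] = {}
        # genes sorted so the longest transcript is written last and wins
        order = sorted(range(len(ref.genes)), key=lambda i: ref.genes[i].cds_length)
        for chrom, seq in ref.sequences.items():
            self._labels[chrom] = np.zeros(len(seq), dtype=np.int8)
            self._owner[chrom] = np.full(len(seq), -1, dtype=np.int32)
        for gi in order:
            g = ref.genes[gi]
            lab = self._labels[g.chromosome]
            own = self._owner[g.chromosome]
            for s, e in g.intron_intervals:
                sl = slice(s - 1, e)
                lab[sl] = np.maximum(lab[sl], _INTRON)
            for s, e in g.cds_intervals:
                lab[s - 1 : e] = _CDS
                own[s - 1 : e] = gi
        # mask CDS ownership where another gene's CDS later overwrote region
        # (owner already reflects write order = ascending cds_length)
        self.tracts: List[SSRTract] = []
        for chrom, seq in ref.sequences.items():
            self.tracts.extend(
                detect_ssrs(
                    seq,
                    min_copies=ssr_min_copies,
                    min_tract_bp=ssr_min_tract_bp,
                    max_motif=ssr_max_motif,
                    chromosome=chrom,
                )
            )
        # per-gene coding-strand bookkeeping, built lazily
        self._gene_coding: Dict[int, Tuple[str, List[int], Dict[int, int]]] = {}

    # -- gene helpers -------------------------------------------------

    def _coding_info(self, gi: int) -> Tuple[str, List[int], Dict[int, int]]:
        """Coding sequence of gene ``gi``, the genomic position (1-based)
        of each coding offset, and the inverse map."""
        if gi not in self._gene_coding:
            g = self.ref.genes[gi]
            cds = g.coding_sequence(self.ref.sequences)
            positions: List[int] = []
            for s, e in g.cds_intervals:
                positions.extend(range(s, e + 1))
            if g.strand == "-":
                positions.reverse()
            self._gene_coding[gi] = (cds, positions, {p: i for i, p in enumerate(positions)})
        return self._gene_coding[gi]

    # -- site inventory -----------------------------------------------

    def site_inventory(self) -> SiteInventory:
        region_sites = {"CDS": 0, "intron": 0, "intergenic": 0}
        total = 0
        context_counts = {c: 0 for c in all_contexts()}
        for chrom, seq in self.ref.sequences.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            codes = np.full(arr.shape, -1, dtype=np.int8)
            for i, b in enumerate(BASES):
                codes[arr == ord(b)] = i
            valid = codes >= 0
            total += int(valid.sum())
            lab = self._labels[chrom]
            for code, name in _REGION_NAME.items():
                region_sites[name] += int(np.sum(valid & (lab == code)))
            if len(codes) >= 3:
                c5, cf, c3 = codes[:-2], codes[1:-1], codes[2:]
                ok = (c5 >= 0) & (cf >= 0) & (c3 >= 0)
                idx = c5[ok] * 16 + cf[ok] * 4 + c3[ok]
                counts = np.bincount(idx, minlength=64)
                for j, ctx in enumerate(all_contexts()):
                    context_counts[ctx] += int(counts[j])

        syn = 0.0
        nonsyn = 0.0
        fourfold = 0
        for gi, g in enumerate(self.ref.genes):
            cds, positions, _ = self._coding_info(gi)
            if len(cds) % 3 != 0:
                raise AnnotationError(f"{g.gene_id}: CDS length not divisible by 3")
            n_codons = len(cds) // 3
            for ci in range(n_codons):
                codon = cds[3 * ci : 3 * ci + 3]
                if any(b not in _BASE_INDEX for b in codon):
                    continue  # codon touches an N: excluded from site counts
                if CODON_AA[codon] == "*" and ci < n_codons - 1:
                    raise AnnotationError(
                        f"{g.gene_id}: internal stop codon at codon {ci + 1}"
                    )
                ff = is_fourfold(codon)
                for off in range(3):
                    gpos = positions[3 * ci + off]
                    if self._owner[g.chromosome][gpos - 1] != gi:
                        continue  # another (longer) gene owns this site
                    f = syn_fraction(codon, off)
                    syn += f
                    nonsyn += 1.0 - f
                    if off == 2 and ff:
                        fourfold += 1
        return SiteInventory(
            analyzable_sites_total=total,
            sites_by_region=region_sites,
            syn_sites=syn,
            nonsyn_sites=nonsyn,
            fourfold_sites=fourfold,
            context_counts=context_counts,
        )

    # -- classification ------------------------------------------------

    def classify(self, rec: MutationRecord) -> MutationAnnotation:
        seq = self.ref.sequences.get(rec.chromosome)
        if seq is None:
            raise DataIntegrityError(f"unknown chromosome {rec.chromosome}")
        pos0 = rec.position - 1
        if pos0 < 0 or pos0 + len(rec.ref_allele) > len(seq):
            raise DataIntegrityError(
                f"{rec.chromosome}:{rec.position} outside chromosome bounds"
            )
        observed = seq[pos0 : pos0 + len(rec.ref_allele)]
        if observed != rec.ref_allele:
            raise DataIntegrityError(
                f"ref allele mismatch at {rec.chromosome}:{rec.position}: "
                f"expected {observed!r}, record says {rec.ref_allele!r} "
                "(wrong reference build?)"
            )

        region = _REGION_NAME[int(self._labels[rec.chromosome][pos0])]
        gi = int(self._owner[rec.chromosome][pos0])
        gene_id = self.ref.genes[gi].gene_id if gi >= 0 else None

        if rec.kind != "BPS":
            return MutationAnnotation(
                record=rec,
                region=region,
                coding_effect=None,
                at_fourfold_site=False,
                spectrum_class=None,
                ts_tv=None,
                context=None,
                in_ssr=indel_in_ssr(rec, self.tracts, self.ssr_flank_bp),
                gene_id=gene_id,
            )

        ref_b, alt_b = rec.ref_allele, rec.alt_allele
        context = None
        if 0 < pos0 < len(seq) - 1:
            tri = seq[pos0 - 1 : pos0 + 2]
            if all(b in _BASE_INDEX for b in tri):
                context = tri

        coding_effect = None
        at_fourfold = False
        if region == "CDS" and gi >= 0:
            g = self.ref.genes[gi]
            cds, _, pos_index = self._coding_info(gi)
            off = pos_index[rec.position]
            ci, cp = divmod(off, 3)
            codon = cds[3 * ci : 3 * ci + 3]
            alt_coding = alt_b if g.strand == "+" else _COMP[alt_b]
            mutated = codon[:cp] + alt_coding + codon[cp + 1 :]
            coding_effect = (
                "synonymous" if CODON_AA[mutated] == CODON_AA[codon] else "non-synonymous"
            )
            at_fourfold = cp == 2 and is_fourfold(codon)

        return MutationAnnotation(
            record=rec,
            region=region,
            coding_effect=coding_effect,
            at_fourfold_site=at_fourfold,
            spectrum_class=spectrum_class_of(ref_b, alt_b),
            ts_tv=ts_tv_of(ref_b, alt_b),
            context=context,
            in_ssr=None,
            gene_id=gene_id,
        )

    def classify_all(self, records: Iterable[MutationRecord]) -> List[MutationAnnotation]:
        return [self.classify(r) for r in records]


def build_site_inventory(ref: ReferenceBundle) -> SiteInventory:
    """Convenience wrapper: inventory of a reference bundle."""
    return GenomeAnnotator(ref).site_inventory()


def classify_mutation(
    rec: MutationRecord,
    ref: ReferenceBundle,
    annotator: Optional[GenomeAnnotator] = None,
) -> MutationAnnotation:
    """Classify one mutation; pass a prebuilt ``GenomeAnnotator`` when
    classifying many records against the same reference."""
    if annotator is None:
        annotator = GenomeAnnotator(ref)
    return annotator.classify(rec)
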