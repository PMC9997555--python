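"""Synthetic reference genomes and simulated MA experiments.

The generator emulates the structure of a fission-yeast-style MA/WGS
study so every downstream stage can be exercised against known truth:

* a small multi-chromosome genome with CDS/intron/intergenic structure
  and planted simple-sequence-repeat (SSR) tracts;
* per-line mutation counts drawn as Poisson(rate x sites x divisions);
* substitution identities sampled from a six-class spectrum, with
  per-site weighting by 64 trinucleotide-context multipliers;
* indels with a tunable bias toward SSR tracts;
* artifact injection (shared dish-mate mutations, low-coverage lines)
  so the QC filters have something to catch.

Every stream of randomness derives from one master seed; per-line
child streams are keyed by the line's stable index, so appending lines
never perturbs earlier ones and identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import SPECTRUM_MAP, all_contexts, detect_ssrs, _is_primitive
from .core import (
    ConfigurationError,
    GeneModel,
    LineMetadata,
    MutationRecord,
    ReferenceBundle,
    SizingError,
    SSRTract,
    revcomp,
)

BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_MIN_GAP = 30  # bp kept clear between features
_SSR_MARGIN = 5  # bp kept between a planted tract and any gene

# Mean/SD of sequencing depth among lines that survive the 30x floor in a
# typical MA/WGS study; draws below the floor are resampled.
_DEPTH_MEAN, _DEPTH_SD, _DEPTH_FLOOR = 49.44, 13.44, 30.0


@dataclass
class GenomeSpec:
    """Parameters of a toy reference genome."""

    n_chromosomes: int = 3
    chrom_length: int = 50_000
    gc_content: float = 0.36
    n_genes: int = 30
    mean_cds_length: int = 900
    intron_probability: float = 0.4
    ssr_density: float = 2.0  # tracts per 10 kb
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length < 1000:
            raise ValueError("chrom_length must be >= 1000")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.mean_cds_length % 3 != 0 or self.mean_cds_length < 150:
            raise ValueError("mean_cds_length must be a multiple of 3, >= 150")
        if self.n_chromosomes < 1 or self.n_genes < 0:
            raise ValueError("need >= 1 chromosome and >= 0 genes")
        if not 0 <= self.intron_probability <= 1:
            raise ValueError("intron_probability must be in [0, 1]")


@dataclass
class ExperimentDesign:
    """Shape of the MA experiment: lines, transfers, divisions, dishes.

    ``total_divisions_*`` optionally overrides ``transfers x
    divisions_per_transfer`` with an empirically estimated division
    total (colony CFU counts rarely land exactly on the nominal
    product)."""

    n_lines_control: int = 80
    n_lines_treatment: int = 90
    transfers: int = 50
    divisions_per_transfer_control: int = 20
    divisions_per_transfer_treatment: int = 17
    lines_per_dish: int = 2
    total_divisions_control: Optional[int] = None
    total_divisions_treatment: Optional[int] = None

    def validate(self) -> None:
        if self.lines_per_dish < 1:
            raise ValueError("lines_per_dish must be >= 1")
        if min(self.n_lines_control, self.n_lines_treatment) < 0:
            raise ValueError("negative line count")

    def divisions(self, group: str) -> int:
        if group == "control":
            return self.total_divisions_control or (
                self.transfers * self.divisions_per_transfer_control
            )
        return self.total_divisions_treatment or (
            self.transfers * self.divisions_per_transfer_treatment
        )


def _control_spectrum() -> Dict[str, float]:
    # class weights shaped like a spontaneous yeast spectrum
    return {
        "A:T->G:C": 11.0,
        "G:C->A:T": 18.0,
        "A:T->T:A": 5.0,
        "A:T->C:G": 5.0,
        "G:C->C:G": 5.0,
        "G:C->T:A": 18.0,
    }


def _treatment_spectrum() -> Dict[str, float]:
    # oxidative-damage-shifted spectrum: G:C->T:A strongly elevated
    return {
        "A:T->G:C": 21.0,
        "G:C->A:T": 27.0,
        "A:T->T:A": 5.0,
        "A:T->C:G": 11.0,
        "G:C->C:G": 5.0,
        "G:C->T:A": 45.0,
    }


@dataclass
class TruthRates:
    """Planted mutational parameters for one group of lines."""

    bps_rate_per_site_per_division: float = 6.86e-11
    indel_rate_per_site_per_division: float = 3.76e-11
    spectrum_weights: Dict[str, float] = field(default_factory=_control_spectrum)
    context_multipliers: Optional[Dict[str, float]] = None
    insertion_fraction: float = 30 / 34
    ssr_bias: float = 1.0

    def validate(self) -> None:
        if min(self.bps_rate_per_site_per_division,
               self.indel_rate_per_site_per_division) < 0:
            raise ValueError("rates must be >= 0")
        if any(w < 0 for w in self.spectrum_weights.values()):
            raise ValueError("spectrum weights must be >= 0")
        if self.context_multipliers is not None and any(
            v <= 0 for v in self.context_multipliers.values()
        ):
            raise ValueError("context multipliers must be > 0")
        for f in (self.insertion_fraction, self.ssr_bias):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")


# ------------------------------------------------------------ genome


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return "".join(BASES[i] for i in idx)


def _sample_coding(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons-2) non-stop codons + one stop codon."""
    body: List[str] = []
    while len(body) < n_codons - 2:
        chunk = _sample_bases(rng, 3 * (n_codons - 2 - len(body)), gc)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in _STOPS:
                body.append(codon)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def generate_genome(spec: GenomeSpec) -> ReferenceBundle:
    """Build a reference bundle from a :class:`GenomeSpec`.

    Every CDS starts with ATG, ends with a stop codon and has no
    internal stop on its coding strand; features never overlap; planted
    SSR tracts are returned as truth in ``ReferenceBundle.ssr_tracts``.
    Identical specs give byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sequences: Dict[str, str] = {}
    genes: List[GeneModel] = []
    tracts: List[SSRTract] = []

    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = spec.chrom_length
        n_genes_c = per_chrom[ci]

        # gene geometry first, so infeasible specs fail before heavy work
        mu_codons = spec.mean_cds_length // 3
        plans = []
        for _ in range(n_genes_c):
            n_codons = max(20, int(round(rng.normal(mu_codons, mu_codons / 6))))
            cds_len = 3 * n_codons
            has_intron = rng.random() < spec.intron_probability
            ilen = int(rng.integers(40, 121)) if has_intron else 0
            c_off = int(rng.integers(3, cds_len - 2)) if has_intron else 0
            plans.append((n_codons, cds_len, ilen, c_off))
        span_total = sum(cds + ilen for _, cds, ilen, _ in plans)
        budget = span_total + (n_genes_c + 1) * _MIN_GAP
        if budget > L:
            raise SizingError(
                f"{chrom}: {n_genes_c} genes need {budget} bp "
                f"(spans {span_total} + gaps) but chrom_length is {L}"
            )
        extra = rng.multinomial(L - budget, [1.0 / (n_genes_c + 1)] * (n_genes_c + 1))
        gaps = [int(g) + _MIN_GAP for g in extra]

        seq = list(_sample_bases(rng, L, spec.gc_content))
        cursor = 0
        gene_spans: List[Tuple[int, int]] = []  # 0-based [start, end)
        for j, (n_codons, cds_len, ilen, c_off) in enumerate(plans):
            cursor += gaps[j]
            gs0 = cursor  # 0-based span start
            span = cds_len + ilen
            strand = "+" if rng.random() < 0.5 else "-"
            coding = _sample_coding(rng, n_codons, spec.gc_content)
            if ilen:
                intron_seq = _sample_bases(rng, ilen, spec.gc_content)
                region = coding[:c_off] + intron_seq + coding[c_off:]
            else:
                region = coding
            if strand == "-":
                region = revcomp(region)
            seq[gs0 : gs0 + span] = region
            gs, ge = gs0 + 1, gs0 + span  # 1-based inclusive
            if ilen:
                if strand == "+":
                    i_start = gs + c_off
                else:
                    i_start = gs + (cds_len - c_off)
                i_end = i_start + ilen - 1
                cds_intervals: Tuple[Tuple[int, int], ...] = (
                    (gs, i_start - 1),
                    (i_end + 1, ge),
                )
            else:
                cds_intervals = ((gs, ge),)
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}_g{j + 1:03d}",
                    chromosome=chrom,
                    strand=strand,
                    cds_intervals=cds_intervals,
                )
            )
            gene_spans.append((gs0, gs0 + span))
            cursor += span

        # plant SSR tracts in the intergenic gaps, clear of gene margins
        free: List[Tuple[int, int]] = []  # 0-based [start, end)
        prev = 0
        for (s, e) in gene_spans:
            if s - _SSR_MARGIN > prev:
                free.append((prev, s - _SSR_MARGIN))
            prev = e + _SSR_MARGIN
        if prev < L:
            free.append((prev, L))
        n_tracts = int(round(spec.ssr_density * L / 10_000))
        for _ in range(n_tracts):
            k = int(rng.integers(1, 4))
            motif = _sample_bases(rng, k, spec.gc_content)
            while not _is_primitive(motif):
                motif = _sample_bases(rng, k, spec.gc_content)
            copies = int(rng.integers(5, 9))
            tlen = k * copies
            feasible = [fi for fi, (s, e) in enumerate(free) if e - s >= tlen + 2]
            if not feasible:
                continue
            fi = feasible[int(rng.integers(0, len(feasible)))]
            s, e = free[fi]
            t0 = int(rng.integers(s + 1, e - tlen))  # 0-based tract start
            seq[t0 : t0 + tlen] = motif * copies
            tracts.append(
                SSRTract(
                    chromosome=chrom,
                    start=t0 + 1,
                    end=t0 + tlen,
                    motif=motif,
                    n_copies=copies,
                )
            )
            free[fi : fi + 1] = [(s, t0 - 1), (t0 + tlen + 1, e)]
            free = [(a, b) for a, b in free if b - a > 0]

        sequences[chrom] = "".join(seq)

    return ReferenceBundle(sequences=sequences, genes=genes, ssr_tracts=tracts)


# -------------------------------------------------------- simulation


@dataclass
class SimulatedExperiment:
    """A simulated MA experiment: reference, per-line mutations,
    metadata, and the planted-truth table."""

    ref: ReferenceBundle
    design: ExperimentDesign
    truths: Dict[str, TruthRates]
    lines: List[LineMetadata]
    mutations: Dict[str, List[MutationRecord]]
    truth_table: pd.DataFrame
    artifacts: Dict[str, list] = field(default_factory=lambda: {
        "shared_pairs": [], "low_depth_lines": []
    })

    def all_mutations(self) -> List[MutationRecord]:
        out: List[MutationRecord] = []
        for line in self.lines:
            out.extend(self.mutations[line.line_id])
        return out

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_fasta(self.ref.sequences, out / "reference.fa")
        mio.write_gff3(self.ref.genes, self.ref.sequences, out / "genes.gff3")
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for line in self.lines:
            mio.write_vcf(
                self.mutations[line.line_id],
                self.ref.sequences,
                vcf_dir / f"{line.line_id}.vcf",
            )
        mio.write_metadata(self.lines, out / "metadata.tsv")
        self.truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "artifacts.json").write_text(json.dumps(self.artifacts, indent=2))


class _SiteSampler:
    """Shared per-experiment sampling machinery over one reference."""

    def __init__(self, ref: ReferenceBundle) -> None:
        self.ref = ref
        self.chroms = list(ref.sequences)
        self.seqs = {c: ref.sequences[c] for c in self.chroms}
        tracts = ref.ssr_tracts
        if tracts is None:
            tracts = []
            for c, s in ref.sequences.items():
                tracts.extend(detect_ssrs(s, chromosome=c))
        self.tracts = [t for t in tracts]
        # global interior positions: (chrom index, 1-based position)
        chrom_idx: List[np.ndarray] = []
        pos: List[np.ndarray] = []
        ctx_code: List[np.ndarray] = []
        for k, c in enumerate(self.chroms):
            arr = np.frombuffer(self.seqs[c].encode("ascii"), dtype=np.uint8)
            codes = np.full(arr.shape, -1, dtype=np.int8)
            for i, b in enumerate(BASES):
                codes[arr == ord(b)] = i
            n = len(arr)
            if n < 3:
                continue
            c5, cf, c3 = codes[:-2], codes[1:-1], codes[2:]
            ok = (c5 >= 0) & (cf >= 0) & (c3 >= 0)
            p = np.nonzero(ok)[0] + 2  # 1-based interior position
            chrom_idx.append(np.full(p.shape, k, dtype=np.int32))
            pos.append(p.astype(np.int64))
            ctx_code.append(
                (c5[ok].astype(np.int32) * 16 + cf[ok] * 4 + c3[ok]).astype(np.int32)
            )
        self.chrom_idx = np.concatenate(chrom_idx)
        self.pos = np.concatenate(pos)
        self.ctx_code = np.concatenate(ctx_code)
        self.focal_code = (self.ctx_code // 4) % 4
        self._ctx_names = all_contexts()
        # indel placement candidates
        in_tract = {
            c: np.zeros(len(self.seqs[c]) + 2, dtype=bool) for c in self.chroms
        }
        near_tract = {
            c: np.zeros(len(self.seqs[c]) + 2, dtype=bool) for c in self.chroms
        }
        margin = 6
        for t in self.tracts:
            ch = in_tract[t.chromosome]
            ch[t.start : t.end + 1] = True
            nt = near_tract[t.chromosome]
            nt[max(1, t.start - margin) : min(len(nt) - 1, t.end + margin) + 1] = True
        self.tract_positions: List[Tuple[str, int, int]] = [
            (t.chromosome, t.start, t.end) for t in self.tracts
        ]
        self.non_tract: List[Tuple[str, np.ndarray]] = []
        for c in self.chroms:
            L = len(self.seqs[c])
            cand = np.arange(2, L - 4)  # 1-based anchors with room for a 3-bp deletion
            cand = cand[~near_tract[c][cand]]
            self.non_tract.append((c, cand))
        self._non_tract_sizes = np.array([len(v) for _, v in self.non_tract])

    def sampling_probs(self, truth: "TruthRates") -> Optional[np.ndarray]:
        """Per-site selection probabilities for substitutions: context
        multipliers times an indicator that the focal base can mutate
        under the spectrum weights (e.g. a pure G:C spectrum never
        selects an A or T site).  ``None`` means uniform."""
        base_w = np.array([
            sum(
                truth.spectrum_weights.get(SPECTRUM_MAP[(r, b)], 0.0)
                for b in BASES
                if b != r
            )
            for r in BASES
        ])
        if base_w.sum() <= 0:
            raise ConfigurationError("spectrum weights are all zero")
        mask = base_w[self.focal_code] > 0
        mult = np.ones(64)
        if truth.context_multipliers:
            for i, name in enumerate(self._ctx_names):
                if name in truth.context_multipliers:
                    mult[i] = truth.context_multipliers[name]
        if mask.all() and np.allclose(mult, 1.0):
            return None
        w = mult[self.ctx_code] * mask
        if w.sum() <= 0:
            raise ConfigurationError(
                "no analyzable site is mutable under the spectrum weights"
            )
        return w / w.sum()

    def sample_bps_sites(
        self, rng: np.random.Generator, n: int, p: Optional[np.ndarray]
    ) -> List[Tuple[str, int]]:
        total = len(self.pos)
        if n > total:
            raise ConfigurationError(
                f"requested {n} substitution sites but only {total} available"
            )
        idx = rng.choice(total, size=n, replace=False, p=p)
        return [
            (self.chroms[self.chrom_idx[i]], int(self.pos[i])) for i in idx
        ]


def _alt_base(
    rng: np.random.Generator, ref_base: str, weights: Dict[str, float]
) -> str:
    alts = [b for b in BASES if b != ref_base]
    w = np.array([weights.get(SPECTRUM_MAP[(ref_base, b)], 0.0) for b in alts])
    if w.sum() <= 0:
        raise ConfigurationError(
            f"spectrum weights give no alternative for ref base {ref_base}"
        )
    return alts[rng.choice(3, p=w / w.sum())]


def simulate_ma_lines(
    ref: ReferenceBundle,
    truth: TruthRates,
    design: ExperimentDesign,
    seed: int,
    treatment_truth: Optional[TruthRates] = None,
    sites_per_line: Optional[int] = None,
) -> SimulatedExperiment:
    """Simulate an MA experiment over ``ref``.

    ``truth`` applies to the control group; ``treatment_truth`` (default:
    same as control) to the treatment group.  ``sites_per_line``
    overrides the analyzable-site count used both for Poisson means and
    metadata (defaults to the reference's non-N total).
    """
    design.validate()
    truth.validate()
    t_truth = treatment_truth if treatment_truth is not None else truth
    t_truth.validate()
    sampler = _SiteSampler(ref)
    if sampler.pos.size == 0:
        raise ConfigurationError("reference has zero analyzable interior sites")
    n_sites = sites_per_line if sites_per_line is not None else ref.analyzable_sites

    lines: List[LineMetadata] = []
    mutations: Dict[str, List[MutationRecord]] = {}
    truth_rows: List[dict] = []
    group_specs = [
        ("control", design.n_lines_control, "C",
         design.divisions_per_transfer_control, truth),
        ("treatment", design.n_lines_treatment, "T",
         design.divisions_per_transfer_treatment, t_truth),
    ]
    weights_by_group = {
        g: sampler.sampling_probs(t)
        if t.bps_rate_per_site_per_division > 0 else None
        for g, _, _, _, t in group_specs
    }
    global_index = 0
    for group, n_lines, prefix, dpt, g_truth in group_specs:
        total_div = design.divisions(group)
        for i in range(n_lines):
            line_id = f"{prefix}{i + 1:03d}"
            dish_id = f"{prefix}D{i // design.lines_per_dish + 1:03d}"
            rng = np.random.default_rng([seed, global_index])
            global_index += 1

            recs: List[MutationRecord] = []
            used: set = set()
            lam_bps = g_truth.bps_rate_per_site_per_division * n_sites * total_div
            n_bps = int(rng.poisson(lam_bps)) if lam_bps > 0 else 0
            sites = sampler.sample_bps_sites(rng, n_bps, weights_by_group[group])
            for chrom, p1 in sites:
                ref_b = ref.sequences[chrom][p1 - 1]
                alt_b = _alt_base(rng, ref_b, g_truth.spectrum_weights)
                recs.append(MutationRecord(line_id, chrom, p1, ref_b, alt_b))
                used.add((chrom, p1))
                truth_rows.append(
                    dict(line_id=line_id, chromosome=chrom, position=p1,
                         ref_allele=ref_b, alt_allele=alt_b, kind="BPS",
                         in_ssr=False, origin="spontaneous")
                )

            lam_ind = g_truth.indel_rate_per_site_per_division * n_sites * total_div
            n_ind = int(rng.poisson(lam_ind)) if lam_ind > 0 else 0
            for _ in range(n_ind):
                rec, placed_in_ssr = _place_indel(rng, sampler, ref, g_truth,
                                                  line_id, used)
                recs.append(rec)
                truth_rows.append(
                    dict(line_id=line_id, chromosome=rec.chromosome,
                         position=rec.position, ref_allele=rec.ref_allele,
                         alt_allele=rec.alt_allele, kind=rec.kind,
                         in_ssr=placed_in_ssr, origin="spontaneous")
                )

            depth = float(rng.normal(_DEPTH_MEAN, _DEPTH_SD))
            while depth < _DEPTH_FLOOR:
                depth = float(rng.normal(_DEPTH_MEAN, _DEPTH_SD))
            lines.append(
                LineMetadata(
                    line_id=line_id,
                    group=group,
                    dish_id=dish_id,
                    transfers=design.transfers,
                    divisions_per_transfer=dpt,
                    mean_depth=round(depth, 2),
                    analyzable_sites=n_sites,
                    total_divisions=total_div,
                )
            )
            mutations[line_id] = recs

    truth_table = pd.DataFrame(
        truth_rows,
        columns=["line_id", "chromosome", "position", "ref_allele",
                 "alt_allele", "kind", "in_ssr", "origin"],
    )
    return SimulatedExperiment(
        ref=ref,
        design=design,
        truths={"control": truth, "treatment": t_truth},
        lines=lines,
        mutations=mutations,
        truth_table=truth_table,
    )


def _place_indel(
    rng: np.random.Generator,
    sampler: _SiteSampler,
    ref: ReferenceBundle,
    truth: TruthRates,
    line_id: str,
    used: set,
) -> Tuple[MutationRecord, bool]:
    is_insertion = rng.random() < truth.insertion_fraction
    in_ssr = rng.random() < truth.ssr_bias
    length = int(rng.integers(1, 4))
    for _ in range(200):
        if in_ssr:
            if not sampler.tract_positions:
                raise ConfigurationError(
                    "ssr_bias > 0 but the reference has no SSR tracts"
                )
            chrom, s, e = sampler.tract_positions[
                int(rng.integers(0, len(sampler.tract_positions)))
            ]
            hi = min(e - 1, len(ref.sequences[chrom]) - length - 1)
            if hi < s:
                continue
            p1 = int(rng.integers(s, hi + 1))
        else:
            k = int(rng.choice(len(sampler.non_tract),
                               p=sampler._non_tract_sizes / sampler._non_tract_sizes.sum()))
            chrom, cand = sampler.non_tract[k]
            if len(cand) == 0:
                continue
            p1 = int(cand[int(rng.integers(0, len(cand)))])  # already 1-based
        if (chrom, p1) in used:
            continue
        used.add((chrom, p1))
        seq = ref.sequences[chrom]
        anchor = seq[p1 - 1]
        if anchor == "N":
            continue
        if is_insertion:
            if in_ssr:
                # slippage-style: duplicate the bases following the anchor
                ins = seq[p1 : p1 + length]
            else:
                ins = _sample_bases(rng, length, 0.5)
            if "N" in ins or len(ins) < length:
                continue
            return MutationRecord(line_id, chrom, p1, anchor, anchor + ins), in_ssr
        deleted = seq[p1 : p1 + length]
        if "N" in deleted or len(deleted) < length:
            continue
        return MutationRecord(line_id, chrom, p1, anchor + deleted, anchor), in_ssr
    raise ConfigurationError("could not place indel after 200 attempts")


# ---------------------------------------------------------- artifacts


def inject_artifacts(
    sim: SimulatedExperiment,
    n_shared_pairs: int,
    n_low_depth: int,
    seed: int,
    group: Optional[str] = None,
) -> SimulatedExperiment:
    """Return a copy of ``sim`` with QC-triggering artifacts planted.

    ``n_shared_pairs`` two-line dishes receive one identical mutation in
    both dish-mates (the cross-contamination signature); ``n_low_depth``
    further lines (never dish-mates of a contaminated pair, so the two
    filters act on disjoint lines) get mean depth below the 30x floor.
    """
    new = SimulatedExperiment(
        ref=sim.ref,
        design=sim.design,
        truths=dict(sim.truths),
        lines=[replace(m) for m in sim.lines],
        mutations={k: list(v) for k, v in sim.mutations.items()},
        truth_table=sim.truth_table.copy(),
        artifacts=copy.deepcopy(sim.artifacts),
    )
    eligible = [m for m in new.lines if group is None or m.group == group]
    dishes: Dict[str, List[LineMetadata]] = {}
    for m in eligible:
        dishes.setdefault(m.dish_id, []).append(m)
    pairs = [d for d in sorted(dishes) if len(dishes[d]) == 2]
    if n_shared_pairs > len(pairs):
        raise ConfigurationError(
            f"asked for {n_shared_pairs} shared pairs but only "
            f"{len(pairs)} two-line dishes available"
        )
    rng = np.random.default_rng([seed, 982451653])
    chosen = (
        sorted(rng.choice(len(pairs), size=n_shared_pairs, replace=False).tolist())
        if n_shared_pairs
        else []
    )
    chroms = list(new.ref.sequences)
    lengths = np.array([len(new.ref.sequences[c]) for c in chroms], dtype=float)
    truth_rows = []
    contaminated_dishes = set()
    for di in chosen:
        dish = pairs[di]
        contaminated_dishes.add(dish)
        pair = dishes[dish]
        taken = {
            (r.chromosome, r.position)
            for m in pair
            for r in new.mutations[m.line_id]
        }
        while True:
            ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom = chroms[ci]
            p1 = int(rng.integers(2, len(new.ref.sequences[chrom])))
            if (chrom, p1) in taken:
                continue
            ref_b = new.ref.sequences[chrom][p1 - 1]
            if ref_b == "N":
                continue
            break
        alt_b = [b for b in BASES if b != ref_b][int(rng.integers(0, 3))]
        for m in pair:
            new.mutations[m.line_id].append(
                MutationRecord(m.line_id, chrom, p1, ref_b, alt_b)
            )
            truth_rows.append(
                dict(line_id=m.line_id, chromosome=chrom, position=p1,
                     ref_allele=ref_b, alt_allele=alt_b, kind="BPS",
                     in_ssr=False, origin="shared_artifact")
            )
        new.artifacts["shared_pairs"].append(
            {"dish_id": dish, "lines": [m.line_id for m in pair],
             "chromosome": chrom, "position": p1, "ref": ref_b, "alt": alt_b}
        )

    depth_pool = [m for m in eligible if m.dish_id not in contaminated_dishes]
    if n_low_depth > len(depth_pool):
        raise ConfigurationError(
            f"asked for {n_low_depth} low-depth lines but only "
            f"{len(depth_pool)} lines outside contaminated dishes"
        )
    if n_low_depth:
        picks = sorted(
            rng.choice(len(depth_pool), size=n_low_depth, replace=False).tolist()
        )
        for pi in picks:
            m = depth_pool[pi]
            m.mean_depth = round(float(rng.uniform(12.0, 28.0)), 2)
            new.artifacts["low_depth_lines"].append(
                {"line_id": m.line_id, "mean_depth": m.mean_depth}
            )
    if truth_rows:
        new.truth_table = pd.concat(
            [new.truth_table, pd.DataFrame(truth_rows)], ignore_index=True
        )
    return new


# ------------------------------------------------------ study factories


def study_design() -> ExperimentDesign:
    """The sequenced-line design of the study being emulated: 80 control
    and 90 treated lines, two per dish, 50 transfers at ~20 and ~17
    divisions per transfer, with empirically estimated division totals
    of 1,009 and 865."""
    return ExperimentDesign(
        n_lines_control=80,
        n_lines_treatment=90,
        transfers=50,
        divisions_per_transfer_control=20,
        divisions_per_transfer_treatment=17,
        lines_per_dish=2,
        total_divisions_control=1009,
        total_divisions_treatment=865,
    )


def study_fixture(
    seed: int = 0,
    chrom_length: int = 40_000,
    n_chromosomes: int = 3,
    n_genes: int = 24,
) -> SimulatedExperiment:
    """A study-shaped synthetic experiment on a scaled-down genome.

    The genome is orders of magnitude smaller than a real yeast genome,
    so per-site rates are scaled up to preserve the study's expected
    mutation totals over the kept lines (62/34 control BPS/indels, 114/23
    for the treatment).  Three control and one treatment dish pairs carry
    a shared mutation and four/three lines get sub-30x depth, so QC
    keeps 73 and 86 lines.
    """
    spec = GenomeSpec(
        n_chromosomes=n_chromosomes,
        chrom_length=chrom_length,
        gc_content=0.36,
        n_genes=n_genes,
        mean_cds_length=900,
        intron_probability=0.4,
        ssr_density=2.0,
        seed=seed,
    )
    ref = generate_genome(spec)
    design = study_design()
    n = ref.analyzable_sites
    exp_c = 73 * 1009 * n  # site-division exposure over kept control lines
    exp_t = 86 * 865 * n
    control = TruthRates(
        bps_rate_per_site_per_division=62 / exp_c,
        indel_rate_per_site_per_division=34 / exp_c,
        spectrum_weights=_control_spectrum(),
        insertion_fraction=30 / 34,
        ssr_bias=1.0,
    )
    treatment = TruthRates(
        bps_rate_per_site_per_division=114 / exp_t,
        indel_rate_per_site_per_division=23 / exp_t,
        spectrum_weights=_treatment_spectrum(),
        insertion_fraction=19 / 23,
        ssr_bias=0.6522,
    )
    sim = simulate_ma_lines(ref, control, design, seed, treatment_truth=treatment)
    sim = inject_artifacts(sim, 3, 4, seed, group="control")
    sim = inject_artifacts(sim, 1, 3, seed + 1, group="treatment")
    return sim
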