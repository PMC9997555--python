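"""Estimators and statistics for MA mutation data.

The central quantity is the mean mutation rate

    mu = m / sum_i (N_i x T_i)

where ``m`` is the mutation count over all lines passing QC, and each
line contributes its analyzable sites ``N_i`` times the cell divisions
``T_i`` it experienced (per-genome rates drop the ``N_i`` factor).
Uncertainty on ``m`` is quantified by the exact (Garwood) Poisson
interval built from chi-square quantiles; every categorical comparison
(non-synonymous vs synonymous counts against site totals, spectrum
differences between groups, rate ratios on unequal exposures) uses a
1-d.f. chi-square with Yates continuity correction.

Also here: the division estimator ``T = log2 N`` from colony CFU
counts, the harmonic-mean effective population size of a bottlenecked
expansion, the per-gene Poisson mutation-enrichment scan with
Benjamini–Hochberg control, the moment dispersion statistic
``alpha = (V - mu) / mu^2`` for RNAseq replicate counts, and efficiency
of plating for survival curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import (
    SPECTRUM_CLASSES,
    TRANSITION_CLASSES,
    TRANSVERSION_CLASSES,
    all_contexts,
    SiteInventory,
)
from .core import GeneModel, LineMetadata, MutationAnnotation, RateEstimate


# ------------------------------------------------- division bookkeeping


def divisions_from_cfu(cells: float) -> float:
    """Divisions between transfers from a colony's cell count, assuming
    exponential growth from a single cell: T = log2(cells)."""
    if cells < 1:
        raise ValueError("cell count must be >= 1")
    return math.log2(cells)


def effective_population_size(T: int) -> float:
    """Harmonic-mean effective size of one transfer cycle.

    A colony grows from one cell through T doublings, so census size is
    2^i at stage i; the harmonic mean over the T+1 stages is
    (T+1) / sum_{i=0..T} 2^{-i}.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    denom = sum(2.0 ** -i for i in range(int(T) + 1))
    return (T + 1) / denom


# --------------------------------------------------- Poisson intervals


def poisson_ci(m: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count.

    low = chi2.ppf(alpha/2, 2m) / 2 (zero when m = 0) and
    high = chi2.ppf(1 - alpha/2, 2m + 2) / 2.
    """
    if m < 0 or int(m) != m:
        raise ValueError("m must be a nonnegative integer")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if m == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * m)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * m + 2)
    return float(low), float(high)


def mutation_rate(
    m: int,
    lines: Sequence[LineMetadata],
    per: str = "site",
    category_sites: Optional[Dict[str, float] | float] = None,
    level: float = 0.95,
) -> RateEstimate:
    """Rate estimate with exact Poisson interval for ``m`` mutations
    over the exposure contributed by QC-passing ``lines``.

    ``per='site'`` uses sum(N_i x T_i); ``per='genome'`` uses sum(T_i).
    ``category_sites`` replaces each line's analyzable-site count for
    category-specific rates (four-fold sites, CDS sites, ...): either a
    single number applied to every line or a per-line mapping.
    """
    if per not in ("site", "genome"):
        raise ValueError("per must be 'site' or 'genome'")
    exposure = 0.0
    for line in lines:
        if per == "genome":
            exposure += line.total_divisions
            continue
        if category_sites is None:
            n = line.analyzable_sites
        elif isinstance(category_sites, dict):
            n = category_sites[line.line_id]
        else:
            n = category_sites
        exposure += n * line.total_divisions
    if exposure <= 0:
        raise ValueError("zero exposure: no lines or empty category")
    low, high = poisson_ci(m, level=level)
    return RateEstimate(
        m=m,
        exposure=exposure,
        rate=m / exposure,
        ci_low=low / exposure,
        ci_high=high / exposure,
        level=level,
    )


# ------------------------------------------------------ spectrum table


@dataclass
class SpectrumTable:
    """Counts and proportions in the layout of a mutational-features
    table: six substitution classes grouped into transitions and
    transversions, plus insertion/deletion counts."""

    counts: Dict[str, int]
    ts_count: int
    tv_count: int
    ts_tv_ratio: float  # NaN when no transversions
    insertions: int
    deletions: int
    ins_del_ratio: float  # NaN when no deletions
    proportions: Dict[str, float]  # within the class's Ts or Tv block

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "ts_count": self.ts_count,
            "tv_count": self.tv_count,
            "ts_tv_ratio": self.ts_tv_ratio,
            "insertions": self.insertions,
            "deletions": self.deletions,
            "ins_del_ratio": self.ins_del_ratio,
            "proportions": dict(self.proportions),
        }


def spectrum_table(annotations: Iterable[MutationAnnotation]) -> SpectrumTable:
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    ins = dels = 0
    for a in annotations:
        if a.record.kind == "BPS":
            counts[a.spectrum_class] += 1
        elif a.record.kind == "insertion":
            ins += 1
        else:
            dels += 1
    ts = sum(counts[c] for c in TRANSITION_CLASSES)
    tv = sum(counts[c] for c in TRANSVERSION_CLASSES)
    props = {}
    for c in SPECTRUM_CLASSES:
        block = ts if c in TRANSITION_CLASSES else tv
        props[c] = counts[c] / block if block else float("nan")
    return SpectrumTable(
        counts=counts,
        ts_count=ts,
        tv_count=tv,
        ts_tv_ratio=ts / tv if tv else float("nan"),
        insertions=ins,
        deletions=dels,
        ins_del_ratio=ins / dels if dels else float("nan"),
        proportions=props,
    )


# ---------------------------------------------------- chi-square tests


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p}


def _yates_gof(observed: Sequence[float], expected: Sequence[float]) -> Chi2Result:
    chi2 = 0.0
    for o, e in zip(observed, expected):
        d = max(abs(o - e) - 0.5, 0.0)  # correction clamped at zero
        chi2 += d * d / e
    return Chi2Result(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def gof_test_ns_s(
    nonsyn_obs: int, syn_obs: int, nonsyn_sites: float, syn_sites: float
) -> Chi2Result:
    """Does the observed non-synonymous/synonymous split match the
    genomic site composition?  Under neutrality (drift dominating
    selection) the counts should split proportionally to the numbers of
    non-synonymous and synonymous sites; a 1-d.f. Yates-corrected
    goodness-of-fit chi-square tests that."""
    if min(nonsyn_obs, syn_obs) < 0 or min(nonsyn_sites, syn_sites) <= 0:
        raise ValueError("counts must be >= 0 and site totals > 0")
    total = nonsyn_obs + syn_obs
    if total == 0:
        return Chi2Result(float("nan"), 1, float("nan"))
    f = nonsyn_sites / (nonsyn_sites + syn_sites)
    return _yates_gof([nonsyn_obs, syn_obs], [total * f, total * (1 - f)])


def count_comparison_test(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-square with Yates continuity correction on the 2x2
    table [[a, b], [c, d]] (e.g. transitions/transversions in control
    vs treatment)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return Chi2Result(float("nan"), 1, float("nan"))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p))


@dataclass(frozen=True)
class RateRatioResult:
    chi2: float
    df: int
    p: float
    ratio: float  # (m2/e2) / (m1/e1)

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p, "ratio": self.ratio}


def rate_ratio_test(
    m1: int, e1: float, m2: float, e2: float
) -> RateRatioResult:
    """Compare two Poisson rates on unequal exposures.

    Conditional on the total count, the split is binomial with success
    probability proportional to the exposures; the Yates-corrected
    1-d.f. goodness-of-fit chi-square against that expectation
    approximates the exact conditional binomial test.
    """
    if min(e1, e2) <= 0:
        raise ValueError("exposures must be > 0")
    r1, r2 = m1 / e1, m2 / e2
    ratio = r2 / r1 if r1 > 0 else float("inf") if r2 > 0 else float("nan")
    total = m1 + m2
    if total == 0:
        return RateRatioResult(float("nan"), 1, float("nan"), ratio)
    f = e1 / (e1 + e2)
    gof = _yates_gof([m1, m2], [total * f, total * (1 - f)])
    return RateRatioResult(chi2=gof.chi2, df=1, p=gof.p, ratio=ratio)


# ------------------------------------------------ context rate matrix


@dataclass
class ContextRateMatrix:
    """Per-trinucleotide-context mutation rates, in 1e-10 per site per
    division units; cells with no context sites carry NaN, not zero."""

    table: pd.DataFrame  # columns: context, ctx5, focal, ctx3, count, sites, exposure, rate_1e10

    def cell(self, context: str) -> pd.Series:
        return self.table.set_index("context").loc[context]

    def to_frame_16x4(self) -> pd.DataFrame:
        """The heat-map layout: 16 rows keyed by (5', 3') flanks, four
        focal-base columns."""
        t = self.table
        wide = t.pivot_table(
            index=["ctx5", "ctx3"], columns="focal", values="rate_1e10",
            aggfunc="first", dropna=False,
        )
        return wide


def context_rate_matrix(
    annotations: Iterable[MutationAnnotation],
    inventory: SiteInventory,
    lines: Sequence[LineMetadata],
) -> ContextRateMatrix:
    """Rate per context cell: BPS count in that context divided by
    (context sites x total divisions over QC-passing lines)."""
    total_div = sum(line.total_divisions for line in lines)
    counts = {c: 0 for c in all_contexts()}
    for a in annotations:
        if a.record.kind == "BPS" and a.context is not None:
            counts[a.context] += 1
    rows = []
    for ctx in all_contexts():
        sites = inventory.context_counts.get(ctx, 0)
        exposure = sites * total_div
        rate = counts[ctx] / exposure * 1e10 if exposure > 0 else float("nan")
        rows.append(
            dict(context=ctx, ctx5=ctx[0], focal=ctx[1], ctx3=ctx[2],
                 count=counts[ctx], sites=sites, exposure=exposure,
                 rate_1e10=rate)
        )
    return ContextRateMatrix(table=pd.DataFrame(rows))


# --------------------------------------------------- enrichment scan


def gene_enrichment_scan(
    annotations: Iterable[MutationAnnotation],
    genes: Sequence[GeneModel],
    genome_rate: RateEstimate,
    lines: Sequence[LineMetadata],
    bh_level: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Poisson test for mutation enrichment (a sign of positive
    selection that would bias MA rate estimates).

    Expected count per gene is CDS length x per-site rate x total
    divisions over lines; the p-value is the Poisson upper tail
    P(X >= observed) and q-values are Benjamini-Hochberg.
    """
    total_div = sum(line.total_divisions for line in lines)
    observed: Dict[str, int] = {g.gene_id: 0 for g in genes}
    for a in annotations:
        if a.record.kind == "BPS" and a.region == "CDS" and a.gene_id in observed:
            observed[a.gene_id] += 1
    rows = []
    for g in genes:
        lam = g.cds_length * genome_rate.rate * total_div
        obs = observed[g.gene_id]
        p = float(stats.poisson.sf(obs - 1, lam)) if obs > 0 else 1.0
        rows.append(
            dict(gene_id=g.gene_id, cds_length=g.cds_length,
                 observed=obs, expected=lam, p=min(p, 1.0))
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["bh_q"] = q
        df["enriched"] = df["bh_q"] < bh_level
    else:
        df["bh_q"] = []
        df["enriched"] = []
    return df


# --------------------------------------------------------- dispersion


@dataclass(frozen=True)
class DispersionStat:
    gene_id: str
    mean: float
    variance: float
    alpha: float  # (V - mu) / mu^2; NaN when mu = 0


def gene_dispersion(counts: pd.DataFrame) -> List[DispersionStat]:
    """Moment dispersion alpha = (V - mu) / mu^2 per gene.

    ``counts`` has one row per gene (index = gene id) and one column per
    replicate; V is the sample variance (n-1 denominator).  alpha is 0
    under Poisson noise, > 0 when overdispersed, and -1/mu when the
    replicates agree exactly.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two replicates")
    out = []
    for gene_id, row in counts.iterrows():
        mu = float(row.mean())
        v = float(row.var(ddof=1))
        alpha = (v - mu) / mu**2 if mu > 0 else float("nan")
        out.append(DispersionStat(str(gene_id), mu, v, alpha))
    return out


# ---------------------------------------------------------------- EOP


def efficiency_of_plating(cfu_treated: float, cfu_control: float) -> float:
    """Survival measure: treated colony-forming units divided by control
    colony-forming units."""
    if cfu_control <= 0:
        raise ValueError("control CFU must be > 0")
    if cfu_treated < 0:
        raise ValueError("treated CFU must be >= 0")
    return cfu_treated / cfu_control


def eop_curve(doses: Sequence[float], cfu: Sequence[float]) -> pd.DataFrame:
    """EOP over a dose grid; the first entry is taken as the untreated
    control."""
    if len(doses) != len(cfu) or not doses:
        raise ValueError("doses and cfu must be equal-length, non-empty")
    control = cfu[0]
    return pd.DataFrame(
        {"dose": list(doses),
         "eop": [efficiency_of_plating(x, control) for x in cfu]}
    )
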