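"""Synthetic multi-population haplotype panels with known tagging truth.

The generator uses a founder-mosaic model: a pool of founder haplotypes is
drawn with independent per-site allele frequencies, and each population's
haplotypes are built as mosaics of that pool, switching source founder
between adjacent sites with a fixed probability.  More switching (extra
rounds) means faster LD decay; resampling a small number of founders
(a bottleneck) produces drift and possible monomorphism.  On top of this
background, *planted proxies* copy the tag SNP's column exactly (perfect
LD) in the populations where tagging should survive, and are re-randomized
elsewhere to destroy the correlation.

Truth is **measured, not assumed**: after the panel is built, the
TruthTable is computed from the finished allele matrix with the same LD
definitions the pipeline uses, so tests compare the pipeline against
direct measurement rather than against generator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ld_core
from .panel_io import (
    MISSING,
    HaplotypePanel,
    PopulationMap,
    VariantRecord,
    population_panel,
)

__all__ = [
    "PopulationSpec",
    "SyntheticScenario",
    "TruthRow",
    "TruthTable",
    "generate_panel",
    "write_vcf",
    "paperlike_scenario",
]

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class PopulationSpec:
    """One population sample in a scenario.

    ``extra_switch_rounds`` applies additional rounds of mosaic
    recombination (faster LD decay relative to the founders);
    ``drift_bottleneck`` resamples that many founders (with replacement)
    as the population's ancestral pool (None = no bottleneck).
    """

    code: str
    region: str
    n_samples: int
    extra_switch_rounds: int = 0
    drift_bottleneck: int | None = None


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a synthetic study; one seed drives everything."""

    n_founders: int
    positions: tuple[int, ...]
    switch_prob: float
    populations: tuple[PopulationSpec, ...]
    tag_index: int
    planted_proxies: tuple[tuple[int, frozenset[str]], ...]
    seed: int
    monomorphic_tag_pops: frozenset[str] = frozenset()
    contig: str = "1"
    ref_pop: str | None = None  # default: first population
    windows_kb: tuple[int, ...] = (5, 10, 50, 100)
    r2_threshold: float = 0.80
    ld_mode: str = "genotype"

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def reference_pop(self) -> str:
        return self.ref_pop or self.populations[0].code

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        pos = list(self.positions)
        if pos != sorted(set(pos)):
            raise ValueError("positions must be strictly increasing")
        if not (0.0 <= self.switch_prob <= 1.0):
            raise ValueError("switch_prob must be in [0, 1]")
        if not (0 <= self.tag_index < self.n_variants):
            raise ValueError(f"tag_index {self.tag_index} out of range")
        codes = [p.code for p in self.populations]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate population codes")
        for p in self.populations:
            if p.n_samples < 2:
                raise ValueError(f"population {p.code}: need >= 2 samples")
            if p.drift_bottleneck is not None and p.drift_bottleneck < 1:
                raise ValueError(
                    f"population {p.code}: drift_bottleneck must be >= 1 "
                    "founder (use None for no bottleneck)"
                )
        for idx, preserved in self.planted_proxies:
            if idx == self.tag_index:
                raise ValueError("planted proxy coincides with the tag")
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"proxy index {idx} out of range")
            unknown = set(preserved) - set(codes)
            if unknown:
                raise ValueError(f"proxy preserves unknown pops {unknown}")
        if self.reference_pop() in self.monomorphic_tag_pops:
            raise ValueError(
                "tag cannot be monomorphic in the reference population"
            )


@dataclass(frozen=True)
class TruthRow:
    n_candidates: int
    n_tagged: int
    proportion: float


@dataclass
class TruthTable:
    """Measured tagging truth for a generated panel."""

    ref_pop: str
    threshold: float
    windows_kb: tuple[int, ...]
    candidates: dict[int, tuple[int, ...]]  # window -> candidate indices
    rows: dict[tuple[str, int], TruthRow]  # (pop, window) -> truth
    tag_monomorphic: dict[str, bool]

    def proportion(self, pop: str, window_kb: int) -> float:
        return self.rows[(pop, window_kb)].proportion

    def to_frame(self, pmap: PopulationMap | None = None) -> pd.DataFrame:
        recs = []
        for (pop, w), row in sorted(self.rows.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            recs.append(
                {
                    "population": pop,
                    "region": pmap.region_of(pop) if pmap else "",
                    "window_kb": w,
                    "n_candidates": row.n_candidates,
                    "n_tagged": row.n_tagged,
                    "proportion": row.proportion,
                    "tag_monomorphic": self.tag_monomorphic[pop],
                }
            )
        return pd.DataFrame(recs)

    def write_tsv(self, path: str, pmap: PopulationMap | None = None) -> None:
        df = self.to_frame(pmap)
        df["proportion"] = df["proportion"].map(lambda p: f"{p:.6f}")
        df.to_csv(path, sep="\t", index=False)


def _mosaic(pool: np.ndarray, n_out: int, switch_prob: float, rng) -> np.ndarray:
    """Build ``n_out`` mosaic haplotypes over ``pool``.

    Each output row starts on a random pool row and switches to a fresh
    random pool row between adjacent sites with probability
    ``switch_prob``; implemented with a forward-fill over switch points.
    """
    n_pool, m = pool.shape
    cand = rng.integers(0, n_pool, size=(n_out, m))
    switch = rng.random(size=(n_out, m)) < switch_prob
    switch[:, 0] = True  # first site always anchors on cand[:, 0]
    last_switch = np.maximum.accumulate(
        np.where(switch, np.arange(m)[None, :], 0), axis=1
    )
    src = np.take_along_axis(cand, last_switch, axis=1)
    return pool[src, np.arange(m)[None, :]]


def generate_panel(
    scenario: SyntheticScenario,
) -> tuple[HaplotypePanel, PopulationMap, TruthTable]:
    """Generate a phased panel, its population map and its measured truth.

    Deterministic in ``scenario.seed``; all randomness flows through named
    substreams (founders / per-population mosaics / proxy re-randomization),
    so the panels of two scenarios differing only in an appended population
    share the other populations' haplotypes.
    """
    scenario.validate()
    m = scenario.n_variants
    f_rng = np.random.default_rng([scenario.seed & 0x7FFFFFFF, 0])
    freqs = f_rng.uniform(0.10, 0.90, size=m)
    founders = (f_rng.random(size=(scenario.n_founders, m)) < freqs).astype(np.int8)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    pop_rows: dict[str, slice] = {}
    row0 = 0
    for k, pop in enumerate(scenario.populations):
        rng = np.random.default_rng([scenario.seed & 0x7FFFFFFF, 1, k])
        pool = founders
        if pop.drift_bottleneck is not None:
            pool = founders[
                rng.integers(0, scenario.n_founders, size=pop.drift_bottleneck)
            ]
        rounds = 1 + pop.extra_switch_rounds
        for r in range(rounds):
            n_out = 2 * pop.n_samples if r == rounds - 1 else pool.shape[0]
            pool = _mosaic(pool, n_out, scenario.switch_prob, rng)
        blocks.append(pool.astype(np.int8))
        ids = [f"{pop.code}_{i:03d}" for i in range(pop.n_samples)]
        sample_ids.extend(ids)
        for s in ids:
            sample_to_pop[s] = pop.code
        pop_to_region[pop.code] = pop.region
        pop_rows[pop.code] = slice(row0, row0 + 2 * pop.n_samples)
        row0 += 2 * pop.n_samples
    alleles = np.concatenate(blocks, axis=0)

    # Force the tag to the reference allele in the designated populations.
    tag = scenario.tag_index
    p_tag_global = float(alleles[:, tag].mean())
    for code in scenario.monomorphic_tag_pops:
        alleles[pop_rows[code], tag] = 0

    # Plant proxies: copy the tag column where tagging is preserved,
    # re-randomize (Bernoulli at the tag's panel-wide frequency) elsewhere.
    p_rng = np.random.default_rng([scenario.seed & 0x7FFFFFFF, 2])
    for idx, preserved in scenario.planted_proxies:
        for pop in scenario.populations:
            rows = pop_rows[pop.code]
            n_rows = rows.stop - rows.start
            if pop.code in preserved:
                alleles[rows, idx] = alleles[rows, tag]
            else:
                alleles[rows, idx] = (
                    p_rng.random(n_rows) < p_tag_global
                ).astype(np.int8)

    variants = [
        VariantRecord(
            contig=scenario.contig,
            pos=int(p),
            vid=f"v{i:05d}",
            ref_allele=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0],
            alt_allele=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1],
        )
        for i, p in enumerate(scenario.positions)
    ]
    panel = HaplotypePanel(
        variants=variants, sample_ids=sample_ids, alleles=alleles, phased=True
    )
    pmap = PopulationMap(
        sample_to_pop=sample_to_pop, pop_to_region=pop_to_region
    )
    truth = _measure_truth(panel, pmap, scenario)
    return panel, pmap, truth


def _measure_truth(
    panel: HaplotypePanel, pmap: PopulationMap, scenario: SyntheticScenario
) -> TruthTable:
    """Measure the tagging truth directly from the finished allele matrix."""
    fn = ld_core.r2_haplotype if scenario.ld_mode == "haplotype" else ld_core.r2_genotype
    ref_pop = scenario.reference_pop()
    ref = population_panel(panel, pmap, ref_pop)
    tag = scenario.tag_index
    pos = panel.positions
    tag_pos = pos[tag]

    pops = [p.code for p in scenario.populations]
    sub = {p: population_panel(panel, pmap, p) for p in pops}

    def mono(sp: HaplotypePanel) -> bool:
        col = sp.alleles[:, tag]
        obs = col[col != MISSING]
        return obs.size == 0 or bool((obs == obs[0]).all())

    tag_mono = {p: mono(sub[p]) for p in pops}
    if tag_mono[ref_pop]:
        raise ValueError("scenario infeasible: tag monomorphic in reference")

    candidates: dict[int, tuple[int, ...]] = {}
    rows: dict[tuple[str, int], TruthRow] = {}
    for w in scenario.windows_kb:
        cand = []
        for j in np.nonzero(np.abs(pos - tag_pos) <= 1000 * w)[0]:
            j = int(j)
            if j == tag:
                continue
            ld = fn(ref, tag, j)
            if ld.defined and ld.r2 >= scenario.r2_threshold:
                cand.append(j)
        candidates[w] = tuple(cand)
        for p in pops:
            if not cand:
                rows[(p, w)] = TruthRow(0, 0, float("nan"))
                continue
            if tag_mono[p]:
                rows[(p, w)] = TruthRow(len(cand), 0, 0.0)
                continue
            n_tag = 0
            for j in cand:
                ld = fn(sub[p], tag, j)
                if ld.defined and ld.r2 >= scenario.r2_threshold:
                    n_tag += 1
            rows[(p, w)] = TruthRow(len(cand), n_tag, n_tag / len(cand))
    return TruthTable(
        ref_pop=ref_pop,
        threshold=scenario.r2_threshold,
        windows_kb=scenario.windows_kb,
        candidates=candidates,
        rows=rows,
        tag_monomorphic=tag_mono,
    )


def write_vcf(
    panel: HaplotypePanel, pmap: PopulationMap, out_prefix: str
) -> tuple[str, str]:
    """Write the panel as phased VCF 4.2 plus a 1000 Genomes-dialect
    population table (``sample<TAB>pop<TAB>super_pop``).

    Returns (vcf_path, panel_table_path).  Monomorphic columns are still
    emitted; sample columns follow panel order.
    """
    vcf_path = f"{out_prefix}.vcf"
    tsv_path = f"{out_prefix}.panel.tsv"
    sep = "|" if panel.phased else "/"
    contigs = []
    for v in panel.variants:
        if v.contig not in contigs:
            contigs.append(v.contig)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tagport-synthetic\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for col, v in enumerate(panel.variants):
            a = panel.alleles[:, col]
            gts = []
            for s in range(panel.n_samples):
                h0, h1 = a[2 * s], a[2 * s + 1]
                g0 = "." if h0 == MISSING else str(int(h0))
                g1 = "." if h1 == MISSING else str(int(h1))
                gts.append(f"{g0}{sep}{g1}")
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for s in panel.sample_ids:
            pop = pmap.sample_to_pop[s]
            fh.write(f"{s}\t{pop}\t{pmap.pop_to_region[pop]}\n")
    return vcf_path, tsv_path


# 26 population samples across 5 continental regions, mirroring the
# cardinality of the 1000 Genomes Phase 3 study design.
_PAPERLIKE_POPS: tuple[tuple[str, str], ...] = (
    ("CEU", "Europe"), ("TSI", "Europe"), ("GBR", "Europe"),
    ("FIN", "Europe"), ("IBS", "Europe"),
    ("CHB", "East Asia"), ("JPT", "East Asia"), ("CHS", "East Asia"),
    ("CDX", "East Asia"), ("KHV", "East Asia"),
    ("GIH", "South Asia"), ("PJL", "South Asia"), ("BEB", "South Asia"),
    ("STU", "South Asia"), ("ITU", "South Asia"),
    ("YRI", "Africa"), ("LWK", "Africa"), ("GWD", "Africa"),
    ("MSL", "Africa"), ("ESN", "Africa"), ("ASW", "Africa"),
    ("ACB", "Africa"),
    ("MXL", "America"), ("PUR", "America"), ("CLM", "America"),
    ("PEL", "America"),
)

# Probability that a planted proxy keeps its correlation with the tag,
# by continental region: graded LD breakdown away from the reference.
_PRESERVE_P = {
    "Europe": 0.92,
    "South Asia": 0.72,
    "East Asia": 0.60,
    "America": 0.65,
    "Africa": 0.20,
}

_EXTRA_ROUNDS = {
    "Europe": 0,
    "South Asia": 1,
    "East Asia": 1,
    "America": 1,
    "Africa": 2,
}


def paperlike_scenario(seed: int) -> SyntheticScenario:
    """A fixed 26-population scenario shaped like the motivating study.

    One European reference population (CEU) in which all planted proxies
    are in perfect LD with the tag; regionally graded LD breakdown
    elsewhere; two African populations in which the tag is monomorphic.
    The associated TruthTable (via :func:`generate_panel`) qualitatively
    reproduces the study's pattern: reference proportion 1.0, nearby
    populations intermediate, distant populations low, monomorphic
    populations 0.
    """
    spacing = 2000
    n_variants = 121
    positions = tuple(1_000_000 + spacing * i for i in range(n_variants))
    tag_index = 60  # center, pos 1,120,000

    # Proxy layout by window: 4 within 5 kb, 4 more within 10 kb, 6 more
    # within 50 kb, 2 more within 100 kb.
    proxy_indices = (
        58, 59, 61, 62,
        56, 57, 63, 64,
        44, 48, 52, 68, 72, 76,
        30, 90,
    )
    mono_pops = frozenset({"ESN", "MSL"})
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 99])
    proxies = []
    for idx in proxy_indices:
        preserved = {"CEU"}
        for code, region in _PAPERLIKE_POPS:
            if code == "CEU" or code in mono_pops:
                continue
            if rng.random() < _PRESERVE_P[region]:
                preserved.add(code)
        proxies.append((idx, frozenset(preserved)))

    pops = tuple(
        PopulationSpec(
            code=code,
            region=region,
            n_samples=12,
            extra_switch_rounds=_EXTRA_ROUNDS[region],
            drift_bottleneck=8 if code in ("PEL", "MXL") else None,
        )
        for code, region in _PAPERLIKE_POPS
    )
    return SyntheticScenario(
        n_founders=30,
        positions=positions,
        switch_prob=0.40,
        populations=pops,
        tag_index=tag_index,
        planted_proxies=tuple(proxies),
        seed=seed,
        monomorphic_tag_pops=mono_pops,
        ref_pop="CEU",
        windows_kb=(5, 10, 50, 100),
        r2_threshold=0.80,
        ld_mode="genotype",
    )
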