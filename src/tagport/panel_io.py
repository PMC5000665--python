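"""Phased haplotype panel I/O.

Reads a region of a phased multi-sample VCF into an in-memory haplotype
panel (a 2N x M allele matrix of 0/1/missing over biallelic SNVs), and
reads sample->population assignment tables in the 1000 Genomes panel-file
dialect (``sample<TAB>pop<TAB>super_pop``), with an optional exclusion
list for related individuals.

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "KNOWN_REGIONS",
    "VariantRecord",
    "LoadReport",
    "HaplotypePanel",
    "PopulationMap",
    "parse_region",
    "load_panel",
    "load_population_map",
    "population_panel",
]

#: Sentinel for a missing allele call in the haplotype matrix.
MISSING: int = -1

#: Continental region labels used by the 1000 Genomes panel files.
KNOWN_REGIONS = frozenset(
    {"Europe", "Africa", "East Asia", "South Asia", "America"}
)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic single-nucleotide variant.

    Parameters
    ----------
    contig : str
        Chromosome / contig name.
    pos : int
        1-based position (VCF convention).
    vid : str
        Variant identifier (e.g. an rs number), "." if absent.
    ref_allele, alt_allele : str
        Single-base reference and alternate alleles.
    """

    contig: str
    pos: int
    vid: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"{self.vid}: only single-base alleles allowed "
                f"({self.ref_allele!r}/{self.alt_allele!r})"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.vid}: ref and alt alleles are identical")


@dataclass
class LoadReport:
    """Counts of records kept and dropped while loading a VCF region."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snv: int = 0

    def messages(self) -> list[str]:
        out = []
        if self.n_multiallelic:
            out.append(f"{self.n_multiallelic} site(s) dropped: multi-allelic")
        if self.n_non_snv:
            out.append(f"{self.n_non_snv} site(s) dropped: not a SNV")
        return out


@dataclass
class HaplotypePanel:
    """Phased allele matrix plus its variant and sample annotations.

    ``alleles`` has ``2 * len(sample_ids)`` rows (two consecutive haplotype
    rows per sample, in VCF header order) and ``len(variants)`` columns.
    Entries are 0 (ref), 1 (alt) or :data:`MISSING`.
    """

    variants: list[VariantRecord]
    sample_ids: list[str]
    alleles: np.ndarray
    phased: bool = True
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"allele matrix has {self.alleles.shape[0]} rows, expected "
                f"2 x {len(self.sample_ids)} samples"
            )
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError(
                f"allele matrix has {self.alleles.shape[1]} columns for "
                f"{len(self.variants)} variants"
            )
        keys = [(v.contig, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise ValueError("variants must be sorted by (contig, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def variant_index(self, vid: str) -> int:
        """Column index of the variant with identifier ``vid``."""
        for i, v in enumerate(self.variants):
            if v.vid == vid:
                return i
        raise KeyError(f"variant id {vid!r} not present in panel")

    def subset_samples(self, sample_ids: list[str]) -> "HaplotypePanel":
        """Row-subset to the given samples (kept in panel order)."""
        wanted = set(sample_ids)
        keep = [s for s in self.sample_ids if s in wanted]
        missing = wanted - set(keep)
        if missing:
            raise KeyError(
                f"sample id(s) absent from panel: {sorted(missing)}"
            )
        rows = []
        index = {s: i for i, s in enumerate(self.sample_ids)}
        for s in keep:
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return HaplotypePanel(
            variants=list(self.variants),
            sample_ids=keep,
            alleles=self.alleles[rows, :].copy(),
            phased=self.phased,
        )


@dataclass
class PopulationMap:
    """Sample -> population -> continental region assignments.

    ``excluded_samples`` (e.g. related individuals) never appear in any
    population's working panel.
    """

    sample_to_pop: dict[str, str]
    pop_to_region: dict[str, str]
    excluded_samples: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def populations(self) -> list[str]:
        return sorted(self.pop_to_region)

    def region_of(self, pop_code: str) -> str:
        try:
            return self.pop_to_region[pop_code]
        except KeyError:
            raise KeyError(f"unknown population code {pop_code!r}") from None

    def usable_samples(self, pop_code: str) -> list[str]:
        """Non-excluded samples assigned to ``pop_code`` (table order)."""
        if pop_code not in self.pop_to_region:
            raise KeyError(f"unknown population code {pop_code!r}")
        return [
            s
            for s, p in self.sample_to_pop.items()
            if p == pop_code and s not in self.excluded_samples
        ]


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``"contig:start-end"`` (1-based inclusive; commas allowed)."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValueError(
            f"malformed region {region!r}; expected 'contig:start-end'"
        )
    contig = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start < 1 or end < start:
        raise ValueError(f"invalid region span {start}-{end}")
    return contig, start, end


def _is_biallelic_snv(ref: str, alts: list[str]) -> tuple[bool, str]:
    """Classify a VCF record; returns (keep, drop_reason)."""
    if len(alts) != 1:
        return False, "multiallelic"
    if len(ref) != 1 or len(alts[0]) != 1:
        return False, "non_snv"
    if ref.upper() not in _BASES or alts[0].upper() not in _BASES:
        return False, "non_snv"
    return True, ""


def load_panel(
    vcf_path: str,
    region: str | None = None,
    keep_samples: set[str] | None = None,
) -> HaplotypePanel:
    """Load a (region of a) phased VCF into a :class:`HaplotypePanel`.

    Only biallelic SNVs are retained; multi-allelic sites and indels are
    dropped and counted in ``panel.load_report``.  The ``phased`` flag
    reflects the GT separators observed: it is True only when every
    non-missing genotype in the loaded region is phased.

    Parameters
    ----------
    vcf_path : str
        Path to a VCF 4.x file (plain or bgzipped).
    region : str, optional
        ``"contig:start-end"``, 1-based inclusive.  When omitted the whole
        file is loaded.
    keep_samples : set of str, optional
        Restrict to these samples (header order preserved).  An unknown
        sample id raises ``KeyError`` naming it.
    """
    try:
        vcf = VCF(vcf_path, gts012=False)
    except OSError as exc:
        raise FileNotFoundError(f"cannot open VCF {vcf_path!r}: {exc}") from exc

    header_samples = list(vcf.samples)
    if keep_samples is not None:
        unknown = set(keep_samples) - set(header_samples)
        if unknown:
            raise KeyError(
                "sample id(s) not in VCF header: "
                + ", ".join(sorted(unknown))
            )
        samples = [s for s in header_samples if s in keep_samples]
    else:
        samples = header_samples
    if not samples:
        raise ValueError("no samples selected from VCF header")
    sample_pos = {s: i for i, s in enumerate(header_samples)}
    sel = np.array([sample_pos[s] for s in samples], dtype=np.intp)

    want = None
    if region is not None:
        contig, start, end = parse_region(region)
        known = set(vcf.seqnames)
        # seqnames can be empty for header-less plain VCFs; then filter only.
        if known and contig not in known:
            raise ValueError(
                f"contig {contig!r} not present in VCF {vcf_path!r}"
            )
        want = (contig, start, end)

    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    report = LoadReport()
    phased = True
    saw_any_gt = False
    for v in vcf:
        if want is not None:
            contig, start, end = want
            if v.CHROM != contig or not (start <= v.POS <= end):
                continue
        keep, reason = _is_biallelic_snv(v.REF, v.ALT)
        if not keep:
            if reason == "multiallelic":
                report.n_multiallelic += 1
            else:
                report.n_non_snv += 1
            continue
        gts = v.genotype.array()  # (n_samples, 3): a0, a1, phased flag
        gts = gts[sel]
        col = gts[:, :2].astype(np.int16)
        col[col < 0] = MISSING
        nonmiss = col >= 0
        if nonmiss.any():
            saw_any_gt = True
            # A genotype row is phased when its phase flag is set; missing
            # calls do not count against phasing.
            row_has_call = nonmiss.any(axis=1)
            if not np.all(gts[row_has_call, 2] > 0):
                phased = False
        records.append(
            VariantRecord(
                contig=v.CHROM,
                pos=v.POS,
                vid=v.ID if v.ID else f"{v.CHROM}:{v.POS}",
                ref_allele=v.REF.upper(),
                alt_allele=v.ALT[0].upper(),
            )
        )
        columns.append(col.reshape(-1).astype(np.int8))
        report.n_kept += 1

    if records:
        order = sorted(
            range(len(records)), key=lambda i: (records[i].contig, records[i].pos)
        )
        records = [records[i] for i in order]
        alleles = np.stack([columns[i] for i in order], axis=1)
    else:
        alleles = np.zeros((2 * len(samples), 0), dtype=np.int8)

    return HaplotypePanel(
        variants=records,
        sample_ids=samples,
        alleles=alleles,
        phased=phased and saw_any_gt,
        load_report=report,
    )


def _read_exclusions(path: str) -> set[str]:
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def load_population_map(
    panel_table_path: str,
    exclusion_path: str | None = None,
) -> PopulationMap:
    """Read a sample->population->region table plus optional exclusions.

    The table is tab- or comma-separated with a header row; the first three
    columns are interpreted as sample id, population code, region label
    (the 1000 Genomes panel-file dialect ``sample pop super_pop``).  A
    sample listed twice with conflicting populations is an error; region
    labels outside the five continental regions are kept verbatim with a
    warning; populations whose samples are all excluded are flagged in
    ``warnings``.
    """
    with open(panel_table_path) as fh:
        text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(
            f"population table {panel_table_path!r} needs >= 3 columns "
            "(sample, pop, region)"
        )
    df = df.iloc[:, :3]
    df.columns = ["sample", "pop", "region"]
    df = df.dropna(subset=["sample", "pop"])

    warnings: list[str] = []
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    for sample, pop, region in df.itertuples(index=False):
        region = "" if pd.isna(region) else str(region).strip()
        sample, pop = str(sample).strip(), str(pop).strip()
        prev = sample_to_pop.get(sample)
        if prev is not None and prev != pop:
            raise ValueError(
                f"sample {sample!r} listed with conflicting populations "
                f"{prev!r} and {pop!r}"
            )
        sample_to_pop[sample] = pop
        if pop in pop_to_region and pop_to_region[pop] != region:
            raise ValueError(
                f"population {pop!r} listed with conflicting regions "
                f"{pop_to_region[pop]!r} and {region!r}"
            )
        pop_to_region[pop] = region
        if region and region not in KNOWN_REGIONS:
            msg = f"unknown region label {region!r} (kept verbatim)"
            if msg not in warnings:
                warnings.append(msg)

    excluded = _read_exclusions(exclusion_path) if exclusion_path else set()
    pmap = PopulationMap(
        sample_to_pop=sample_to_pop,
        pop_to_region=pop_to_region,
        excluded_samples=excluded,
        warnings=warnings,
    )
    for pop in pmap.populations():
        if not pmap.usable_samples(pop):
            pmap.warnings.append(
                f"population {pop!r} has zero usable samples after exclusions"
            )
    return pmap


def population_panel(
    panel: HaplotypePanel, pmap: PopulationMap, pop_code: str
) -> HaplotypePanel:
    """Sub-panel of the non-excluded samples assigned to one population.

    The variant list (columns) is unchanged, even for columns that are
    monomorphic within the population — downstream LD code decides what a
    monomorphic column means.
    """
    usable = set(pmap.usable_samples(pop_code))
    present = [s for s in panel.sample_ids if s in usable]
    if not present:
        raise ValueError(
            f"population {pop_code!r} has no usable samples in this panel"
        )
    return panel.subset_samples(present)
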