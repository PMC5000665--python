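"""Pairwise linkage disequilibrium (r²) between variant columns.

Two estimators are provided:

* haplotype mode — the textbook definition on phased haplotype
  frequencies, r² = D² / (p_A q_A p_B q_B) with D = p_AB − p_A p_B;
* genotype mode — the squared Pearson correlation of per-sample allele
  dosages (0/1/2), which is what PLINK computes by default.

Both use pairwise-complete observations.  When either locus is
monomorphic among the complete observations (or fewer than two remain)
the value is *undefined* rather than zero: a monomorphic tag SNP carries
no information, and downstream code treats undefined as "not tagged".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import MISSING, HaplotypePanel

__all__ = ["LdValue", "r2_haplotype", "r2_genotype", "r2_matrix_around", "write_ld_table"]


@dataclass(frozen=True)
class LdValue:
    """One pairwise r² with its provenance.

    ``r2`` is NaN when ``defined`` is False.  ``n_used`` counts haplotypes
    (haplotype mode) or samples (genotype mode) complete at both loci.
    """

    r2: float
    n_used: int
    mode: str
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not (-1e-9 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError(f"r2 out of [0,1]: {self.r2}")


def _undefined(n_used: int, mode: str) -> LdValue:
    return LdValue(r2=float("nan"), n_used=n_used, mode=mode, defined=False)


def _check_index(panel: HaplotypePanel, idx: int) -> None:
    if not (0 <= idx < panel.n_variants):
        raise IndexError(
            f"variant index {idx} out of range [0, {panel.n_variants})"
        )


def r2_haplotype(panel: HaplotypePanel, i: int, j: int) -> LdValue:
    """r² from phased haplotype frequencies at columns ``i`` and ``j``.

    Over haplotype rows complete at both columns, with alt-allele
    frequencies p_A, p_B and joint alt-alt frequency p_AB:
    D = p_AB − p_A p_B and r² = D² / (p_A(1−p_A) p_B(1−p_B)).
    """
    if not panel.phased:
        raise ValueError(
            "panel is not phased: haplotype-mode r2 is unavailable; "
            "use genotype mode (r2_genotype)"
        )
    _check_index(panel, i)
    _check_index(panel, j)
    a = panel.alleles[:, i]
    b = panel.alleles[:, j]
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n < 2:
        return _undefined(n, "haplotype")
    a = a[ok].astype(np.float64)
    b = b[ok].astype(np.float64)
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return _undefined(n, "haplotype")
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    return LdValue(r2=min(float(r2), 1.0), n_used=n, mode="haplotype", defined=True)


def _dosages(panel: HaplotypePanel, idx: int) -> np.ndarray:
    """Per-sample alt-allele dosage (0/1/2), MISSING if either call is."""
    col = panel.alleles[:, idx].reshape(-1, 2)
    dose = col.sum(axis=1).astype(np.int16)
    dose[(col == MISSING).any(axis=1)] = MISSING
    return dose


def r2_genotype(panel: HaplotypePanel, i: int, j: int) -> LdValue:
    """r² as the squared Pearson correlation of genotype dosages.

    Works for phased or unphased panels; this is the PLINK-default
    estimator.  A constant dosage vector at either locus (among
    pairwise-complete samples) makes the value undefined.
    """
    _check_index(panel, i)
    _check_index(panel, j)
    x = _dosages(panel, i)
    y = _dosages(panel, j)
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n < 2:
        return _undefined(n, "genotype")
    x = x[ok].astype(np.float64)
    y = y[ok].astype(np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return _undefined(n, "genotype")
    sxy = float(xc @ yc)
    r2 = (sxy * sxy) / (sxx * syy)
    return LdValue(r2=min(float(r2), 1.0), n_used=n, mode="genotype", defined=True)


_MODES = {"haplotype": r2_haplotype, "genotype": r2_genotype}


def r2_matrix_around(
    panel: HaplotypePanel,
    anchor: int,
    max_dist: int,
    mode: str = "genotype",
) -> dict[int, LdValue]:
    """r² of the anchor variant against every variant within ``max_dist`` bp.

    Returns a mapping variant index -> :class:`LdValue` for all variants
    with ``|pos - anchor_pos| <= max_dist``, anchor excluded.  Memory is
    proportional to the number of variants in range.
    """
    _check_index(panel, anchor)
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if mode not in _MODES:
        raise ValueError(f"unknown LD mode {mode!r}")
    fn = _MODES[mode]
    pos = panel.positions
    anchor_contig = panel.variants[anchor].contig
    in_range = np.nonzero(np.abs(pos - pos[anchor]) <= max_dist)[0]
    out: dict[int, LdValue] = {}
    for j in in_range:
        j = int(j)
        if j == anchor or panel.variants[j].contig != anchor_contig:
            continue
        out[j] = fn(panel, anchor, j)
    return out


def write_ld_table(
    panel: HaplotypePanel,
    anchor: int,
    mapping: dict[int, LdValue],
    out_path: str,
) -> None:
    """Dump an r² mapping as TSV (vid, pos, distance, r2, n_used, defined)."""
    anchor_pos = panel.variants[anchor].pos
    with open(out_path, "w") as fh:
        fh.write("vid\tpos\tdistance\tr2\tn_used\tdefined\n")
        for j in sorted(mapping):
            v = panel.variants[j]
            ld = mapping[j]
            r2 = f"{ld.r2:.6f}" if ld.defined else "NA"
            fh.write(
                f"{v.vid}\t{v.pos}\t{v.pos - anchor_pos}\t{r2}\t"
                f"{ld.n_used}\t{ld.defined}\n"
            )
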