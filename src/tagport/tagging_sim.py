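"""Cross-population tag-SNP portability evaluation.

The procedure: in a *reference* population (CEU in the motivating study),
enumerate every variant within a distance window of the tag SNP whose r²
with the tag meets a threshold (default 0.80) — these are the candidate
"functional" variants the tag could be standing in for.  Then, in every
other population, measure how often a candidate drawn uniformly at random
is still tagged (defined r² ≥ threshold) there.

Two evaluation modes are provided.  *Exact* enumeration computes the
estimand n_tagged / n_candidates directly.  *Monte Carlo* reproduces the
original resampling procedure: n_sims seeded uniform draws with
replacement from the candidate set.  With a finite candidate set the MC
estimand equals the exact proportion, so exact mode is the default.

An undefined r² in the target population — the tag or the candidate is
monomorphic there — counts as not tagged: a monomorphic tag carries no
information about any nearby variant.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld_core import r2_genotype, r2_haplotype
from .panel_io import MISSING, HaplotypePanel, PopulationMap, population_panel

__all__ = [
    "StudyConfig",
    "CandidateSet",
    "TaggingResult",
    "derive_seed",
    "enumerate_candidates",
    "evaluate_exact",
    "evaluate_monte_carlo",
    "run_study",
    "write_results",
    "read_results",
    "write_candidates",
]

_LD_FN = {"haplotype": r2_haplotype, "genotype": r2_genotype}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one tag-SNP portability study.

    Parameters
    ----------
    tag_vid : str
        Identifier of the tag SNP (e.g. ``rs1333049``).
    tag_pos : int
        Its 1-based position; used to cross-check the panel lookup.
    risk_allele : str
        Reported risk allele; carried through to output metadata only.
    ref_pop : str
        Population in which candidates are enumerated (default ``CEU``).
    windows_kb : tuple of int
        Distance windows in kb, strictly increasing (default 5/10/50/100).
        A window W keeps variants with ``|pos − tag_pos| ≤ 1000·W``.
    r2_threshold : float
        Tagging threshold on r² (default 0.80).
    n_sims : int
        Monte-Carlo draws per (window, population); default 10**6.
    seed : int
        Base seed; per-population streams are derived from it.
    ld_mode : {"genotype", "haplotype"}
        LD estimator (default genotype-dosage correlation, the PLINK
        default).
    eval_mode : {"exact", "monte_carlo", "both"}
    """

    tag_vid: str
    tag_pos: int
    risk_allele: str = "N"
    ref_pop: str = "CEU"
    windows_kb: tuple[int, ...] = (5, 10, 50, 100)
    r2_threshold: float = 0.80
    n_sims: int = 10**6
    seed: int = 0
    ld_mode: str = "genotype"
    eval_mode: str = "exact"

    def __post_init__(self) -> None:
        w = tuple(int(x) for x in self.windows_kb)
        object.__setattr__(self, "windows_kb", w)
        if not w or any(x <= 0 for x in w) or list(w) != sorted(set(w)):
            raise ValueError("windows_kb must be strictly increasing positive")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.ld_mode not in _LD_FN:
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.eval_mode not in ("exact", "monte_carlo", "both"):
            raise ValueError(f"unknown eval_mode {self.eval_mode!r}")


@dataclass(frozen=True)
class CandidateSet:
    """Candidate "functional" variants for one (tag, window, ref pop)."""

    tag_vid: str
    tag_index: int
    window_kb: int
    ref_pop: str
    threshold: float
    candidates: tuple[int, ...]  # column indices, ordered by position

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class TaggingResult:
    """Tagging outcome for one (tag, window, target population).

    ``proportion`` is NaN when ``n_candidates`` is zero (reported
    explicitly, never silently dropped).
    """

    tag_vid: str
    window_kb: int
    target_pop: str
    region: str
    n_candidates: int
    n_tagged: int
    proportion: float
    tag_monomorphic: bool
    mode: str
    n_sims: int | None = None
    seed: int | None = None


def derive_seed(base_seed: int, tag_vid: str, window_kb: int, pop_code: str) -> int:
    """Deterministic per-(tag, window, population) seed.

    Splitting the stream by a stable hash means adding or removing a
    population never perturbs another population's draws.
    """
    key = f"{tag_vid}|{window_kb}|{pop_code}".encode()
    return int((zlib.crc32(key) ^ (base_seed & 0xFFFFFFFF)) & 0x7FFFFFFF)


def _tag_index(panel: HaplotypePanel, cfg: StudyConfig) -> int:
    try:
        idx = panel.variant_index(cfg.tag_vid)
    except KeyError:
        raise KeyError(
            f"tag SNP {cfg.tag_vid!r} not present in panel"
        ) from None
    pos = panel.variants[idx].pos
    if cfg.tag_pos and pos != cfg.tag_pos:
        raise ValueError(
            f"tag SNP {cfg.tag_vid!r} found at position {pos}, "
            f"config says {cfg.tag_pos}"
        )
    return idx


def _is_monomorphic(panel: HaplotypePanel, idx: int) -> bool:
    col = panel.alleles[:, idx]
    obs = col[col != MISSING]
    return obs.size == 0 or bool((obs == obs[0]).all())


def enumerate_candidates(
    ref_panel: HaplotypePanel, cfg: StudyConfig, window_kb: int
) -> CandidateSet:
    """Candidates within ``window_kb`` of the tag, in LD with it in the
    reference population.

    A candidate is any variant (other than the tag itself) with
    ``|pos − tag_pos| ≤ 1000·window_kb`` whose r² with the tag is defined
    and ≥ the threshold.  An empty candidate set is reportable, not an
    error; a tag that is monomorphic in the reference population makes the
    procedure undefined and raises.
    """
    tag = _tag_index(ref_panel, cfg)
    if _is_monomorphic(ref_panel, tag):
        raise ValueError(
            f"tag SNP {cfg.tag_vid!r} is monomorphic in reference "
            f"population {cfg.ref_pop!r}: candidate enumeration undefined"
        )
    fn = _LD_FN[cfg.ld_mode]
    pos = ref_panel.positions
    tag_pos = pos[tag]
    in_win = np.nonzero(np.abs(pos - tag_pos) <= 1000 * window_kb)[0]
    cands = []
    for j in in_win:
        j = int(j)
        if j == tag:
            continue
        ld = fn(ref_panel, tag, j)
        if ld.defined and ld.r2 >= cfg.r2_threshold:
            cands.append(j)
    cands.sort(key=lambda j: (ref_panel.variants[j].pos, j))
    return CandidateSet(
        tag_vid=cfg.tag_vid,
        tag_index=tag,
        window_kb=int(window_kb),
        ref_pop=cfg.ref_pop,
        threshold=cfg.r2_threshold,
        candidates=tuple(cands),
    )


def _tagged_mask(
    cands: CandidateSet, target_panel: HaplotypePanel, cfg: StudyConfig
) -> tuple[np.ndarray, bool]:
    """Per-candidate tagged flags in the target panel, plus tag-monomorphic."""
    if cands.n_candidates == 0:
        raise ValueError(
            "candidate set is empty; report 'no candidates' explicitly "
            "instead of evaluating"
        )
    tag = cands.tag_index
    if not (
        0 <= tag < target_panel.n_variants
        and target_panel.variants[tag].vid == cands.tag_vid
    ):
        raise ValueError(
            "target panel columns are not aligned with the reference panel "
            f"(tag {cands.tag_vid!r} not at column {tag})"
        )
    mono = _is_monomorphic(target_panel, tag)
    fn = _LD_FN[cfg.ld_mode]
    mask = np.zeros(cands.n_candidates, dtype=bool)
    if not mono:
        for k, j in enumerate(cands.candidates):
            ld = fn(target_panel, tag, j)
            mask[k] = ld.defined and ld.r2 >= cands.threshold
    return mask, mono


def evaluate_exact(
    cands: CandidateSet,
    target_panel: HaplotypePanel,
    cfg: StudyConfig,
    target_pop: str = "target",
    region: str = "",
) -> TaggingResult:
    """Exact tagging proportion: n_tagged / n_candidates."""
    mask, mono = _tagged_mask(cands, target_panel, cfg)
    n_tagged = int(mask.sum())
    return TaggingResult(
        tag_vid=cands.tag_vid,
        window_kb=cands.window_kb,
        target_pop=target_pop,
        region=region,
        n_candidates=cands.n_candidates,
        n_tagged=n_tagged,
        proportion=n_tagged / cands.n_candidates,
        tag_monomorphic=mono,
        mode="exact",
    )


def evaluate_monte_carlo(
    cands: CandidateSet,
    target_panel: HaplotypePanel,
    cfg: StudyConfig,
    target_pop: str = "target",
    region: str = "",
    seed: int | None = None,
) -> TaggingResult:
    """Monte-Carlo tagging proportion over ``cfg.n_sims`` uniform draws
    with replacement from the candidate set (seeded, reproducible).

    ``n_tagged`` records the underlying exact count so the binomial
    agreement invariant can be checked against the same result row.
    """
    mask, mono = _tagged_mask(cands, target_panel, cfg)
    use_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    draws = rng.integers(0, cands.n_candidates, size=cfg.n_sims)
    prop = float(mask[draws].mean())
    return TaggingResult(
        tag_vid=cands.tag_vid,
        window_kb=cands.window_kb,
        target_pop=target_pop,
        region=region,
        n_candidates=cands.n_candidates,
        n_tagged=int(mask.sum()),
        proportion=prop,
        tag_monomorphic=mono,
        mode="monte_carlo",
        n_sims=cfg.n_sims,
        seed=use_seed,
    )


def run_study(
    panel: HaplotypePanel, pmap: PopulationMap, cfg: StudyConfig
) -> list[TaggingResult]:
    """Full study: per window, enumerate candidates in the reference
    population once, then evaluate every population (reference included
    as positive control).

    Results are ordered by (window, region, population).  Populations with
    no usable samples are skipped with the error annotated; an empty
    candidate set yields one explicit NaN-proportion row per population.
    """
    ref_panel = population_panel(panel, pmap, cfg.ref_pop)
    pops = sorted(
        pmap.populations(), key=lambda p: (pmap.region_of(p), p)
    )
    results: list[TaggingResult] = []
    for window in cfg.windows_kb:
        try:
            cands = enumerate_candidates(ref_panel, cfg, window)
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"window {window} kb: {exc}") from exc
        for pop in pops:
            region = pmap.region_of(pop)
            try:
                target = population_panel(panel, pmap, pop)
            except ValueError as exc:
                raise ValueError(
                    f"window {window} kb, population {pop}: {exc}"
                ) from exc
            if cands.n_candidates == 0:
                results.append(
                    TaggingResult(
                        tag_vid=cfg.tag_vid,
                        window_kb=window,
                        target_pop=pop,
                        region=region,
                        n_candidates=0,
                        n_tagged=0,
                        proportion=float("nan"),
                        tag_monomorphic=_is_monomorphic(
                            target, cands.tag_index
                        ),
                        mode=cfg.eval_mode if cfg.eval_mode != "both" else "exact",
                    )
                )
                continue
            if cfg.eval_mode in ("exact", "both"):
                results.append(
                    evaluate_exact(cands, target, cfg, target_pop=pop, region=region)
                )
            if cfg.eval_mode in ("monte_carlo", "both"):
                results.append(
                    evaluate_monte_carlo(
                        cands,
                        target,
                        cfg,
                        target_pop=pop,
                        region=region,
                        seed=derive_seed(cfg.seed, cfg.tag_vid, window, pop),
                    )
                )
    return results


_COLUMNS = [
    "tag_vid",
    "window_kb",
    "region",
    "population",
    "n_candidates",
    "n_tagged",
    "proportion",
    "tag_monomorphic",
    "mode",
    "n_sims",
    "seed",
]


def results_frame(results: list[TaggingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "tag_vid": r.tag_vid,
                "window_kb": r.window_kb,
                "region": r.region,
                "population": r.target_pop,
                "n_candidates": r.n_candidates,
                "n_tagged": r.n_tagged,
                "proportion": r.proportion,
                "tag_monomorphic": r.tag_monomorphic,
                "mode": r.mode,
                "n_sims": r.n_sims,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_results(results: list[TaggingResult], out_path: str) -> None:
    """Write results as TSV; proportions at 4 decimals, NaN printed ``NA``."""
    if not results:
        raise ValueError("no results to write")
    df = results_frame(results)
    df["proportion"] = [
        "NA" if not np.isfinite(p) else f"{p:.4f}" for p in df["proportion"]
    ]
    for col in ("n_sims", "seed"):
        df[col] = ["NA" if v is None else str(v) for v in df[col]]
    df.to_csv(out_path, sep="\t", index=False)


def read_results(path: str) -> pd.DataFrame:
    """Read a results TSV back (``NA`` becomes NaN in numeric columns)."""
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False
    )


def write_candidates(
    cands: CandidateSet, ref_panel: HaplotypePanel, cfg: StudyConfig, out_path: str
) -> None:
    """Per-window candidate table: vid, pos, distance to tag, r² in reference."""
    fn = _LD_FN[cfg.ld_mode]
    tag_pos = ref_panel.variants[cands.tag_index].pos
    with open(out_path, "w") as fh:
        fh.write("vid\tpos\tdistance\tr2_ref\n")
        for j in cands.candidates:
            v = ref_panel.variants[j]
            ld = fn(ref_panel, cands.tag_index, j)
            fh.write(f"{v.vid}\t{v.pos}\t{v.pos - tag_pos}\t{ld.r2:.6f}\n")
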