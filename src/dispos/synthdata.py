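"""Benchmark generation: implanting known binding sites into promoter pools.

The construction mirrors the classical implantation protocol: draw
floor(n_sites / 0.7) target promoters so that 70% of them carry exactly one
implanted site, place each site on a uniformly chosen strand at a start
drawn from a uniform or Gaussian positional law, and pair the target set
with an equally sized control set drawn from the same pool without
implants.  A decoy motif can additionally be planted into *every* target
and control promoter, making it over-represented but not differentially
abundant.

Implantation substitutes the site into the promoter (sequence lengths are
preserved, as the positional model requires equal-length input).

``sample_from_model`` draws sequences directly from a ZOOPS parameter set
and is the generator used for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import FlankingModel, PWM, PositionPrior, ZoopsParams, position_pmf
from .seqdata import ALPHABET, Sequence, reverse_complement

#: per sequence id, (start, end, strand, site-string) annotations
SiteAnnotations = dict[str, list[tuple[int, int, str, str]]]


class SynthesisError(ValueError):
    pass


@dataclass
class Placement:
    """Positional law for implant starts: uniform over valid starts, or a
    Gaussian (mean, sd in bp) truncated to valid starts by rejection."""

    kind: Literal["uniform", "gaussian"] = "uniform"
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise SynthesisError(f"unknown placement kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise SynthesisError("gaussian placement needs mean and sd > 0")

    def draw_start(self, n_starts: int, rng: np.random.Generator) -> int:
        if self.kind == "uniform":
            return int(rng.integers(n_starts))
        for _ in range(10_000):
            pos = int(round(rng.normal(self.mean, self.sd)))
            if 0 <= pos < n_starts:
                return pos
        raise SynthesisError(
            "gaussian placement rejected 10000 draws; law incompatible with "
            f"valid start range [0, {n_starts})"
        )


def default_gaussian_placement(L: int, rng: np.random.Generator) -> Placement:
    """Gaussian placement with mean ~ U[0.2 L, 0.8 L] and sd ~ U[L/25, L/8]."""
    return Placement(
        kind="gaussian",
        mean=float(rng.uniform(0.2 * L, 0.8 * L)),
        sd=float(rng.uniform(L / 25.0, L / 8.0)),
    )


@dataclass
class ImplantSpec:
    sites: list[str]
    promoter_pool: list[Sequence]
    placement: Placement = field(default_factory=Placement)
    containment_fraction: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.sites:
            raise SynthesisError("need at least one site to implant")
        if not 0.0 < self.containment_fraction <= 1.0:
            raise SynthesisError("containment_fraction must be in (0, 1]")
        for s in self.sites:
            if any(c not in ALPHABET for c in s):
                raise SynthesisError(f"site {s!r} contains non-ACGT letters")
        if self.promoter_pool:
            L = len(self.promoter_pool[0])
            if any(len(s) > L for s in self.sites):
                raise SynthesisError("site longer than the promoters")


@dataclass
class BenchmarkPair:
    """A target promoter set with annotated implants plus a matched,
    implant-free control set of the same size."""

    target: list[Sequence]
    control: list[Sequence]
    annotations: SiteAnnotations
    tss_offset: int = -500

    def __post_init__(self) -> None:
        if len(self.target) != len(self.control):
            raise SynthesisError("target and control must have equal size")


def benchmark_size(n_sites: int, fraction: float = 0.7) -> int:
    """Number of target promoters such that ``fraction`` of them carry one
    implanted site: floor(n_sites / fraction)."""
    if n_sites < 1:
        raise SynthesisError("need at least one site")
    if not 0.0 < fraction <= 1.0:
        raise SynthesisError("fraction must be in (0, 1]")
    return math.floor(n_sites / fraction)


def _substitute(seq: Sequence, site: str, start: int, strand: str) -> Sequence:
    inserted = site if strand == "+" else reverse_complement(site)
    residues = seq.residues[:start] + inserted + seq.residues[start + len(site):]
    return Sequence(id=seq.id, residues=residues)


def implant_sites(spec: ImplantSpec) -> BenchmarkPair:
    """Build a benchmark pair from an implantation specification.

    N = floor(n_sites / fraction) target promoters are drawn without
    replacement from the pool; n_sites of them receive exactly one site each
    (uniform strand, start from the placement law); another N promoters form
    the control set.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = benchmark_size(len(spec.sites), spec.containment_fraction)
    if len(spec.promoter_pool) < 2 * n:
        raise SynthesisError(
            f"pool of {len(spec.promoter_pool)} promoters too small; "
            f"need at least {2 * n}"
        )
    chosen = rng.choice(len(spec.promoter_pool), size=2 * n, replace=False)
    target = [spec.promoter_pool[i] for i in chosen[:n]]
    control = [spec.promoter_pool[i] for i in chosen[n:]]

    carriers = rng.choice(n, size=len(spec.sites), replace=False)
    annotations: SiteAnnotations = {}
    for site, idx in zip(spec.sites, carriers):
        seq = target[idx]
        n_starts = len(seq) - len(site) + 1
        start = spec.placement.draw_start(n_starts, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        target[idx] = _substitute(seq, site, start, strand)
        annotations.setdefault(seq.id, []).append(
            (start, start + len(site), strand, site)
        )
    return BenchmarkPair(target=target, control=control, annotations=annotations)


def add_decoy(
    pair: BenchmarkPair, decoy_sites: list[str], seed: int = 1,
    max_retries: int = 1000,
) -> BenchmarkPair:
    """Plant one uniformly placed decoy site into every target *and* control
    promoter.

    Decoy placements overlapping an annotated true site are resampled; the
    true-site annotations are returned unchanged.
    """
    if not decoy_sites:
        raise SynthesisError("need at least one decoy site")
    rng = np.random.default_rng(seed)

    def place(seq: Sequence, blocked: list[tuple[int, int]]) -> Sequence:
        site = decoy_sites[int(rng.integers(len(decoy_sites)))]
        n_starts = len(seq) - len(site) + 1
        for _ in range(max_retries):
            start = int(rng.integers(n_starts))
            end = start + len(site)
            if all(end <= s or start >= e for s, e in blocked):
                strand = "+" if rng.random() < 0.5 else "-"
                return _substitute(seq, site, start, strand)
        raise SynthesisError(
            f"no non-overlapping decoy placement found in {seq.id!r} "
            f"after {max_retries} retries"
        )

    target = [
        place(s, [(a, b) for a, b, _, _ in pair.annotations.get(s.id, [])])
        for s in pair.target
    ]
    control = [place(s, []) for s in pair.control]
    return BenchmarkPair(
        target=target,
        control=control,
        annotations={k: list(v) for k, v in pair.annotations.items()},
        tss_offset=pair.tss_offset,
    )


def random_promoters(
    n: int, L: int, rng: np.random.Generator, gc: float = 0.4,
    prefix: str = "prom",
) -> list[Sequence]:
    """I.i.d. promoter pool with the given GC content (plant promoters are
    AT-rich; the default of 0.4 reflects that)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    mat = rng.choice(4, size=(n, L), p=p)
    return [
        Sequence(id=f"{prefix}{i}", residues="".join(ALPHABET[c] for c in row))
        for i, row in enumerate(mat)
    ]


def gc_binned_sample(
    pool: list[Sequence], reference: list[Sequence], n: int,
    rng: np.random.Generator, n_bins: int = 10,
) -> list[Sequence]:
    """Utility: draw ``n`` pool sequences whose GC-content histogram follows
    that of ``reference`` (simple binned sampler, no exact matching)."""

    def gc_of(s: Sequence) -> float:
        return (s.residues.count("G") + s.residues.count("C")) / len(s)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ref_bins = np.clip(
        np.digitize([gc_of(s) for s in reference], edges) - 1, 0, n_bins - 1
    )
    want = np.bincount(
        rng.choice(ref_bins, size=n, replace=True), minlength=n_bins
    )
    pool_bins: dict[int, list[Sequence]] = {}
    for s in pool:
        b = int(np.clip(np.digitize(gc_of(s), edges) - 1, 0, n_bins - 1))
        pool_bins.setdefault(b, []).append(s)
    out: list[Sequence] = []
    for b, k in enumerate(want):
        avail = pool_bins.get(b, [])
        if k > len(avail):
            raise SynthesisError(f"pool exhausted in GC bin {b}")
        idx = rng.choice(len(avail), size=int(k), replace=False)
        out.extend(avail[i] for i in idx)
    return out


def sample_from_model(
    fg: ZoopsParams, n: int, L: int, seed: int = 1, prefix: str = "sim",
) -> tuple[list[Sequence], SiteAnnotations]:
    """Draw ``n`` sequences of length L from the ZOOPS generative law.

    Occurrence with probability p_occ; start from the positional prior;
    strand from the strand weight; site letters column-wise from the PWM
    (written on the drawn strand); all other letters i.i.d. from the
    flanking model.  Annotations record the true placements.
    """
    w = fg.width
    if w > L:
        raise SynthesisError(f"motif width {w} exceeds sequence length {L}")
    rng = np.random.default_rng(seed)
    pos_pmf = position_pmf(fg.position, L, w)
    seqs: list[Sequence] = []
    annotations: SiteAnnotations = {}
    for i in range(n):
        letters = rng.choice(4, size=L, p=fg.flanking.probs)
        sid = f"{prefix}{i}"
        if rng.random() < fg.p_occ:
            u = int(rng.choice(len(pos_pmf), p=pos_pmf))
            site = np.array(
                [rng.choice(4, p=col) for col in fg.pwm.probs], dtype=np.int64
            )
            strand = "+" if rng.random() < fg.strand_weight else "-"
            if strand == "-":
                site = 3 - site[::-1]
            letters[u : u + w] = site
            site_str = "".join(ALPHABET[c] for c in letters[u : u + w])
            annotations[sid] = [(u, u + w, strand, site_str)]
        seqs.append(
            Sequence(id=sid, residues="".join(ALPHABET[c] for c in letters))
        )
    return seqs, annotations


def recovery_benchmark(
    seed: int,
    n_per_class: int = 200,
    L: int = 250,
    w: int = 8,
    p_occ: float = 0.7,
    peak: float = 0.85,
    flanking: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3),
    position: PositionPrior | None = None,
):
    """Standard parameter-recovery study: a known ZOOPS law vs. plain flanks.

    The true motif is a random consensus with per-column peak probability
    ``peak`` (~0.6 bit per column, a strong TF motif); sites are placed by a
    right-skewed positional law concentrated in the upstream half of the
    250-bp window (skew normal, location 60, scale 30, shape 3, with a 10%
    uniform component), emulating a TSS-proximal factor.  The background
    class carries the same flanking composition and no motif.  All
    randomness derives from ``seed``.
    """
    from dataclasses import replace as _replace

    from .seqdata import build_dataset

    rng = np.random.default_rng(seed)
    pwm = np.full((w, 4), (1.0 - peak) / 3.0)
    pwm[np.arange(w), rng.integers(0, 4, w)] = peak
    if position is None:
        position = PositionPrior(gamma=0.1, xi=60.0, omega=30.0, alpha_shape=3.0)
    true = ZoopsParams(
        p_occ=p_occ,
        strand_weight=0.5,
        pwm=PWM(pwm),
        flanking=FlankingModel(np.array(flanking)),
        position=position,
    )
    fg_seed = int(rng.integers(2**31 - 1))
    bg_seed = int(rng.integers(2**31 - 1))
    fg_seqs, annotations = sample_from_model(true, n_per_class, L, seed=fg_seed,
                                             prefix="fg")
    bg_seqs, _ = sample_from_model(_replace(true, p_occ=0.0), n_per_class, L,
                                   seed=bg_seed, prefix="bg")
    data = build_dataset(fg_seqs, bg_seqs, tss_offset=-L)
    return true, data, annotations


def _random_pwm(rng: np.random.Generator, w: int = 8, peak: float = 0.85) -> PWM:
    m = np.full((w, 4), (1.0 - peak) / 3.0)
    m[np.arange(w), rng.integers(0, 4, w)] = peak
    return PWM(m)


def sample_sites_from_pwm(pwm: PWM, n: int, rng: np.random.Generator) -> list[str]:
    """Draw n site strings column-wise from a PWM."""
    return [
        "".join(ALPHABET[rng.choice(4, p=col)] for col in pwm.probs)
        for _ in range(n)
    ]


def decoy_benchmark(
    seed: int, n_sites: int = 100, L: int = 200, pool_size: int = 600
):
    """Implantation study with an equally abundant decoy motif.

    Sites of a random true motif are implanted uniformly into the target
    set; a second, unrelated decoy motif is planted into *every* target and
    control promoter, making it over-represented in both classes but
    differentially abundant in neither.  Returns (true PWM, decoy PWM,
    benchmark pair).
    """
    rng = np.random.default_rng(seed)
    true_pwm = _random_pwm(rng)
    decoy_pwm = _random_pwm(rng)
    pool = random_promoters(pool_size, L, rng, gc=0.4)
    sites = sample_sites_from_pwm(true_pwm, n_sites, rng)
    decoys = sample_sites_from_pwm(decoy_pwm, n_sites, rng)
    pair = implant_sites(
        ImplantSpec(
            sites=sites, promoter_pool=pool, placement=Placement("uniform"),
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    pair = add_decoy(pair, decoys, seed=int(rng.integers(2**31 - 1)))
    return true_pwm, decoy_pwm, pair


def positional_benchmark(
    seed: int, n_sites: int = 140, L: int = 250, pool_size: int = 800,
    mean: float = 60.0, sd: float = 20.0,
):
    """Implantation study with a concentrated Gaussian positional law.

    Returns (true PWM, benchmark pair); the implant positions cluster
    around ``mean`` with spread ``sd``, emulating a TSS-proximal factor.
    """
    rng = np.random.default_rng(seed)
    true_pwm = _random_pwm(rng)
    pool = random_promoters(pool_size, L, rng, gc=0.4)
    sites = sample_sites_from_pwm(true_pwm, n_sites, rng)
    pair = implant_sites(
        ImplantSpec(
            sites=sites, promoter_pool=pool,
            placement=Placement("gaussian", mean=mean, sd=sd),
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    return true_pwm, pair


def annotations_to_intervals(
    annotations: SiteAnnotations,
) -> dict[str, list[tuple[int, int]]]:
    """Drop strand/site metadata, keeping plain intervals for evaluation."""
    return {
        sid: [(a, b) for a, b, _, _ in sites]
        for sid, sites in annotations.items()
    }
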