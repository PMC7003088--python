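"""Synthetic genomic-region architectures.

Each simulated unit is a fixed-length region (default 25 kb) containing a
single, centrally placed multi-exon gene that acts as a QTL.  Regions vary in
gene length, exon number and coding fraction ("selection target"), and each
region carries a selection strength ``S`` drawn uniformly from [-1, 1] that is
transformed into the standard deviation of the Gaussian fitness function as
``S_sigma = 10**-S`` (0.1 = steepest fitness peak, 10 = shallowest).

Exon/intron length distributions are parametric stand-ins for empirical gene
architectures; all knobs are configurable through :class:`ArchParams`.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ArchParams",
    "RegionArchitecture",
    "selection_sigma",
    "sample_region",
    "sample_cohort",
    "cohort_to_tsv",
    "cohort_from_tsv",
    "cohort_to_gff3",
]

_MAX_RESAMPLE = 1000


def selection_sigma(S: float) -> float:
    """Transform selection strength ``S`` in [-1, 1] to a fitness-function SD.

    ``S_sigma = 10**-S``: S=1 gives 0.1 (strong stabilizing/divergent
    selection), S=-1 gives 10 (nearly flat fitness landscape).
    """
    if not -1.0 <= S <= 1.0:
        raise ValueError(f"S must lie in [-1, 1], got {S}")
    return 10.0 ** -S


@dataclass(frozen=True)
class ArchParams:
    """Distribution settings for sampled gene architectures.

    Defaults target 25 kb regions; :meth:`scaled_to` shrinks the length scales
    proportionally for smaller test regions.

    Parameters
    ----------
    exon_n_p
        Success probability of the geometric exon-count distribution;
        exon count is ``1 + Geometric(p)`` capped at ``exon_n_max``.
    exon_len_mu, exon_len_sigma
        Log-normal parameters (natural log scale) of exon length in bp.
    intron_len_mu, intron_len_sigma
        Log-normal parameters of intron length in bp.
    """

    exon_n_p: float = 0.15
    exon_n_max: int = 20
    exon_len_mu: float = float(np.log(150.0))
    exon_len_sigma: float = 0.7
    intron_len_mu: float = float(np.log(1000.0))
    intron_len_sigma: float = 1.0

    def scaled_to(self, length: int, reference_length: int = 25_000) -> "ArchParams":
        """Return parameters with length scales shrunk for a shorter region."""
        if length >= reference_length:
            return self
        shift = float(np.log(length / reference_length))
        return dataclasses.replace(
            self,
            exon_len_mu=self.exon_len_mu + shift,
            intron_len_mu=self.intron_len_mu + shift,
            exon_n_max=min(self.exon_n_max, 8),
        )


@dataclass(frozen=True)
class RegionArchitecture:
    """A region's exon map and selection strength.

    ``exons`` are 0-based half-open intervals, sorted, pairwise disjoint and
    non-adjacent, all inside ``[gene_start, gene_end)`` which itself lies
    inside ``[0, length)``.
    """

    region_id: int
    length: int
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    S: float

    def __post_init__(self) -> None:
        if not 0 <= self.gene_start < self.gene_end <= self.length:
            raise ValueError("gene interval must lie within [0, length)")
        prev_end = None
        for start, end in self.exons:
            if not self.gene_start <= start < end <= self.gene_end:
                raise ValueError("exon outside gene interval")
            if prev_end is not None and start <= prev_end:
                raise ValueError("exons must be sorted, disjoint, non-adjacent")
            prev_end = end
        if not self.exons:
            raise ValueError("a region must contain at least one exon")
        if not -1.0 <= self.S <= 1.0:
            raise ValueError("S out of range")
        if not 0.0 < self.selection_target < 1.0:
            raise ValueError("coding fraction must be in (0, 1)")

    @property
    def S_sigma(self) -> float:
        """Fitness-function SD, ``10**-S``."""
        return selection_sigma(self.S)

    @property
    def exon_n(self) -> int:
        return len(self.exons)

    @property
    def gene_length(self) -> int:
        return self.gene_end - self.gene_start

    @property
    def selection_target(self) -> float:
        """Fraction of the region that is exonic (coding)."""
        return sum(e - s for s, e in self.exons) / self.length

    def exon_mask(self) -> np.ndarray:
        """Boolean array of length ``length``; True at exonic positions."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.exons:
            mask[start:end] = True
        return mask


def _sample_gene(rng: np.random.Generator, params: ArchParams) -> tuple[np.ndarray, np.ndarray]:
    """Draw exon and intron lengths for one gene (unbounded)."""
    n_exons = int(min(1 + rng.geometric(params.exon_n_p), params.exon_n_max))
    exon_lens = np.maximum(
        rng.lognormal(params.exon_len_mu, params.exon_len_sigma, n_exons), 3.0
    ).astype(np.int64)
    intron_lens = np.maximum(
        rng.lognormal(params.intron_len_mu, params.intron_len_sigma, max(n_exons - 1, 0)),
        3.0,
    ).astype(np.int64)
    return exon_lens, intron_lens


def sample_region(
    seed: int | np.random.SeedSequence,
    region_id: int = 0,
    length: int = 25_000,
    arch_params: ArchParams | None = None,
) -> RegionArchitecture:
    """Sample one region architecture; identical seed gives identical region.

    The gene (exons alternating with introns) is placed centrally in the
    region.  Genes that do not fit within 80% of the region are resampled, up
    to a bounded retry count.
    """
    params = arch_params or ArchParams()
    rng = np.random.default_rng(seed)
    S = float(rng.uniform(-1.0, 1.0))
    for _ in range(_MAX_RESAMPLE):
        exon_lens, intron_lens = _sample_gene(rng, params)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        if gene_len <= int(0.8 * length):
            break
    else:
        raise RuntimeError(
            f"could not fit a gene inside a {length} bp region after "
            f"{_MAX_RESAMPLE} attempts; adjust arch_params"
        )
    gene_start = (length - gene_len) // 2
    exons = []
    pos = gene_start
    for i, elen in enumerate(exon_lens):
        exons.append((int(pos), int(pos + elen)))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    return RegionArchitecture(
        region_id=region_id,
        length=length,
        gene_start=gene_start,
        gene_end=int(pos),
        exons=tuple(exons),
        S=S,
    )


def sample_cohort(
    seed: int,
    n_regions: int = 100,
    length: int = 25_000,
    arch_params: ArchParams | None = None,
) -> list[RegionArchitecture]:
    """Sample a cohort of distinct regions (ids ``0..n_regions-1``).

    The same cohort is shared by every treatment and selection regime of an
    experiment, so differences between treatments are attributable to
    demography rather than architecture.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_regions)
    return [
        sample_region(child, region_id=i, length=length, arch_params=arch_params)
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TSV_HEADER = "region_id\tlength\tgene_start\tgene_end\texons\tS"


def cohort_to_tsv(cohort: Sequence[RegionArchitecture], path) -> None:
    """Write a cohort as a BED-like TSV (exons comma-joined as start-end)."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for r in cohort:
            exon_str = ",".join(f"{s}-{e}" for s, e in r.exons)
            fh.write(
                f"{r.region_id}\t{r.length}\t{r.gene_start}\t{r.gene_end}\t"
                f"{exon_str}\t{r.S!r}\n"
            )


def cohort_from_tsv(path) -> list[RegionArchitecture]:
    cohort = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            rid, length, gs, ge, exon_str, S = line.rstrip("\n").split("\t")
            exons = tuple(
                tuple(int(x) for x in part.split("-")) for part in exon_str.split(",")
            )
            cohort.append(
                RegionArchitecture(
                    region_id=int(rid),
                    length=int(length),
                    gene_start=int(gs),
                    gene_end=int(ge),
                    exons=exons,  # type: ignore[arg-type]
                    S=float(S),
                )
            )
    return cohort


def cohort_to_gff3(cohort: Sequence[RegionArchitecture], path) -> None:
    """Write a cohort as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in cohort:
            seqid = f"region_{r.region_id}"
            fh.write(f"##sequence-region {seqid} 1 {r.length}\n")
            fh.write(
                f"{seqid}\tdivergesim\tgene\t{r.gene_start + 1}\t{r.gene_end}\t.\t+\t.\t"
                f"ID=gene_{r.region_id};S={r.S!r}\n"
            )
            for i, (s, e) in enumerate(r.exons):
                fh.write(
                    f"{seqid}\tdivergesim\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID=exon_{r.region_id}.{i};Parent=gene_{r.region_id}\n"
                )
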