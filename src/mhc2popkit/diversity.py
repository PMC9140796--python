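"""Nucleotide and haplotype diversity over codon-site partitions.

All statistics can be restricted to a subset of codons.  The motivating use
case is stratifying the 66-codon MHC class II beta-1 domain into
peptide-binding sites (PBS) -- the codons whose residues contact presented
peptides and which balancing selection keeps polymorphic -- and the non-PBS
remainder.

Statistics reported:

* ``S``  -- number of segregating (polymorphic) nucleotide sites,
* ``K``  -- mean number of pairwise nucleotide differences,
* ``pi`` -- per-site nucleotide diversity, ``K`` / analyzed sites,
* ``Hd`` -- haplotype (gene) diversity, ``n/(n-1) * (1 - sum p_i^2)``,
* mean pairwise p-distance at nucleotide or amino-acid level, with a
  codon-bootstrap standard error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import CodonAlignment, translate


@dataclass(frozen=True)
class SitePartition:
    """A set of 1-based codon indices within an in-frame alignment."""

    pbs_codons: frozenset[int]
    codon_count: int = 66
    label: str = "PBS"

    def __post_init__(self) -> None:
        bad = [c for c in self.pbs_codons if not 1 <= c <= self.codon_count]
        if bad:
            raise ValueError(
                f"codon indices out of range 1..{self.codon_count}: {sorted(bad)}"
            )

    @classmethod
    def from_codons(
        cls, codons: Iterable[int], codon_count: int = 66, label: str = "PBS"
    ) -> "SitePartition":
        return cls(frozenset(codons), codon_count=codon_count, label=label)

    @property
    def non_pbs_codons(self) -> frozenset[int]:
        return frozenset(range(1, self.codon_count + 1)) - self.pbs_codons

    def complement(self, label: str = "non-PBS") -> "SitePartition":
        return SitePartition(self.non_pbs_codons, self.codon_count, label)

    def site_indices(self) -> np.ndarray:
        """0-based nucleotide column indices covered by the codon set."""
        cods = np.array(sorted(self.pbs_codons), dtype=int) - 1
        return (cods[:, None] * 3 + np.arange(3)).ravel()

    def codon_indices(self) -> np.ndarray:
        """0-based codon column indices."""
        return np.array(sorted(self.pbs_codons), dtype=int) - 1


# The 20 codons under diversifying selection used as the peptide-binding-site
# partition for gull MHC class II exon 2 (1-based within the 66-codon frame).
GULL_PBS_CODONS = frozenset(
    (8, 9, 10, 12, 16, 17, 19, 20, 26, 39, 42, 43, 48, 49, 52, 53, 56, 60, 63, 66)
)


def gull_pbs_partition(codon_count: int = 66) -> SitePartition:
    return SitePartition(GULL_PBS_CODONS, codon_count=codon_count, label="PBS(20)")


def _matrix(aln: CodonAlignment) -> np.ndarray:
    """Alignment as an (n, L) array of single-byte strings."""
    return np.array([list(s) for s in aln.seqs], dtype="U1")


def _restrict(mat: np.ndarray, partition: SitePartition | None) -> np.ndarray:
    if partition is None:
        return mat
    return mat[:, partition.site_indices()]


def segregating_sites(aln: CodonAlignment, partition: SitePartition | None = None) -> int:
    """Number of columns with two or more distinct non-N nucleotide states."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = _restrict(_matrix(aln), partition)
    count = 0
    for j in range(mat.shape[1]):
        states = set(mat[:, j]) - {"N"}
        if len(states) >= 2:
            count += 1
    return count


def _pairwise_diff_counts(mat: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise difference counts (pairwise N deletion)."""
    n = mat.shape[0]
    valid = mat != "N"
    out = []
    for i in range(n - 1):
        diff = (mat[i] != mat[i + 1 :]) & valid[i] & valid[i + 1 :]
        out.append(diff.sum(axis=1))
    return np.concatenate(out) if out else np.array([], dtype=int)


def pairwise_diversity(
    aln: CodonAlignment, partition: SitePartition | None = None
) -> tuple[float, float]:
    """Mean pairwise differences K and per-site diversity pi = K / sites.

    When the input is a set of distinct haplotypes the result is the
    unweighted (allele-level) diversity; passing one sequence per individual
    yields the frequency-weighted (population-level) diversity.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = _restrict(_matrix(aln), partition)
    diffs = _pairwise_diff_counts(mat)
    K = float(diffs.mean())
    pi = K / mat.shape[1]
    return K, pi


def haplotype_diversity(seqs: Sequence[str]) -> float:
    """Gene diversity Hd = n/(n-1) * (1 - sum p_i^2) over sequence frequencies."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    freqs = np.array(list(Counter(seqs).values()), dtype=float) / n
    return n / (n - 1) * (1.0 - float(np.sum(freqs**2)))


def _mean_p_distance_from_cols(mat: np.ndarray, missing: str = "N") -> float:
    # missing = 'N' at nucleotide level, 'X' at amino-acid level (where 'N'
    # is asparagine); pairwise deletion.
    valid = mat != missing
    n = mat.shape[0]
    total = 0.0
    npairs = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        sites = both.sum(axis=1)
        diff = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(sites > 0, diff / np.maximum(sites, 1), 0.0)
        total += p.sum()
        npairs += p.size
    return total / npairs


def mean_p_distance(
    aln: CodonAlignment,
    level: str = "nt",
    partition: SitePartition | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean pairwise p-distance with a codon-bootstrap standard error.

    ``level='nt'`` compares nucleotide columns; ``level='aa'`` compares the
    translated peptides.  Bootstrap replicates resample codons (keeping the
    reading frame intact) and the SE is the standard deviation of the mean
    distance across replicates, matching the usual distance-with-SE
    convention for coding alignments.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    if level == "nt":
        mat = _matrix(aln)
    elif level == "aa":
        peps = translate(aln)
        mat = np.array([list(p.aa) for p in peps], dtype="U1")
    else:
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")

    if partition is not None:
        cods = partition.codon_indices()
        if cods.size == 0:
            raise ValueError("empty partition")
    else:
        n_codons = aln.codon_count
        cods = np.arange(n_codons)

    if level == "nt":
        def take(codon_idx: np.ndarray) -> np.ndarray:
            cols = (codon_idx[:, None] * 3 + np.arange(3)).ravel()
            return mat[:, cols]
    else:
        def take(codon_idx: np.ndarray) -> np.ndarray:
            return mat[:, codon_idx]

    missing = "N" if level == "nt" else "X"
    d = _mean_p_distance_from_cols(take(cods), missing)
    if bootstrap_reps <= 0:
        return d, 0.0
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        resampled = rng.choice(cods, size=cods.size, replace=True)
        reps[b] = _mean_p_distance_from_cols(take(resampled), missing)
    return d, float(reps.std(ddof=1))


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    sites: int
    S: int
    K: float
    pi: float
    Hd: float | None
    d_nt: float
    d_nt_se: float
    d_aa: float
    d_aa_se: float
    label: str = "all"


def diversity_summary(
    aln: CodonAlignment,
    partition: SitePartition | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    label: str = "all",
) -> DiversitySummary:
    """Bundle S, K, pi, Hd and p-distances for one codon partition."""
    S = segregating_sites(aln, partition)
    K, pi = pairwise_diversity(aln, partition)
    Hd = haplotype_diversity(aln.seqs) if aln.n >= 2 else None
    d_nt, se_nt = mean_p_distance(aln, "nt", partition, bootstrap_reps, seed)
    d_aa, se_aa = mean_p_distance(aln, "aa", partition, bootstrap_reps, seed)
    sites = 3 * len(partition.pbs_codons) if partition is not None else aln.length
    return DiversitySummary(
        n=aln.n, sites=sites, S=S, K=K, pi=pi, Hd=Hd,
        d_nt=d_nt, d_nt_se=se_nt, d_aa=d_aa, d_aa_se=se_aa, label=label,
    )
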