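"""Synthetic clone libraries and coalescent samples.

Two generators give every stage of the pipeline a testable input with known
truth:

* :func:`simulate_clone_library` emulates a clone-based MHC genotyping
  dataset: a two-locus allele pool diverged at fixed sites, nonsynonymous
  variation concentrated at designated peptide-binding codons, occasional
  stop-codon pseudogenes, 1-6 haplotypes per individual, 8-24 clones per
  individual across two PCR replicates, and per-base PCR error.  The
  accompanying :class:`SimulationTruth` is sufficient to score allele
  classification exactly.

* :func:`simulate_coalescent_sample` draws an n-coalescent under the
  sudden-expansion demography (pairwise coalescence hazard 1/theta1 recent,
  1/theta0 ancient, change at tau in mutational time) with infinite-sites
  mutations mapped onto distinct positions of an L-site sequence.

The default clone-library parameters mirror the gull study system this
package models: 68 individuals, a 23 + 36 allele pool over two loci, two
pseudogenes' worth of stop-bearing alleles, and the 20-codon
peptide-binding-site partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import CloneRecord, CodonAlignment, make_alignment, has_internal_stop
from .diversity import SitePartition, gull_pbs_partition
from .allele_validation import AlleleClass

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

# standard-code translation for internal use
from .selection import _CODON_INDEX, _translate_codon  # noqa: E402


def _aa(codon: str) -> str:
    return _translate_codon(_CODON_INDEX[codon])


@dataclass(frozen=True)
class PoolAllele:
    haplotype_id: str
    seq: str
    locus: str
    is_pseudogene: bool


@dataclass
class SimulationTruth:
    allele_pool: dict[str, PoolAllele]
    individual_assignments: dict[str, frozenset[str]]  # individual -> haplotype ids
    parameters: dict = field(default_factory=dict)

    def expected_classes(self) -> dict[str, AlleleClass]:
        """Expected classification (sequence -> class) for assigned alleles.

        Assumes zero PCR error and the generator's clone-allocation
        guarantees (>= 3 clones per haplotype per individual, >= 2 PCRs).
        """
        carriers: dict[str, int] = {}
        for hap_ids in self.individual_assignments.values():
            for hid in hap_ids:
                carriers[hid] = carriers.get(hid, 0) + 1
        out: dict[str, AlleleClass] = {}
        for hid, n_car in carriers.items():
            allele = self.allele_pool[hid]
            if allele.is_pseudogene:
                out[allele.seq] = AlleleClass.PSEUDOGENE
            elif n_car >= 2:
                out[allele.seq] = AlleleClass.PUTATIVE_TRUE
            else:
                out[allele.seq] = AlleleClass.UNIQUE
        return out


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def _mutate_allele(
    base_seq: str,
    n_steps: int,
    pbs_sites: set[int],
    multiplier: float,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> str:
    """Apply ``n_steps`` accepted point mutations to a coding sequence.

    Proposals creating stop codons are rejected.  At peptide-binding codons
    nonsynonymous changes are always accepted and synonymous ones thinned by
    1/multiplier; outside them the thinning is reversed, which concentrates
    amino-acid variation at the designated codons.
    """
    seq = list(base_seq)
    accepted = 0
    tries = 0
    while accepted < n_steps and tries < max_tries:
        tries += 1
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = _BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        cod_idx = pos // 3
        codon_old = "".join(seq[3 * cod_idx : 3 * cod_idx + 3])
        codon_new = codon_old[: pos % 3] + new + codon_old[pos % 3 + 1 :]
        if codon_new in _STOPS:
            continue
        nonsyn = _aa(codon_old) != _aa(codon_new)
        in_pbs = (cod_idx + 1) in pbs_sites
        if multiplier > 1.0:
            if in_pbs:
                accept = nonsyn or rng.random() < 1.0 / multiplier
            else:
                accept = (not nonsyn) or rng.random() < 1.0 / multiplier
        else:
            accept = True
        if not accept:
            continue
        seq[pos] = new
        accepted += 1
    return "".join(seq)


def _inject_stop(seq: str, rng: np.random.Generator) -> str:
    """Replace an internal codon with a stop codon."""
    n_codons = len(seq) // 3
    cod = int(rng.integers(1, n_codons - 1))  # avoid first and last codon
    stop = _STOPS[int(rng.integers(0, 3))]
    return seq[: 3 * cod] + stop + seq[3 * cod + 3 :]


def simulate_clone_library(
    n_individuals: int = 68,
    alleles_per_locus: tuple[int, int] = (23, 36),
    pbs_codons: SitePartition | None = None,
    pbs_nonsyn_multiplier: float = 4.0,
    haplotypes_per_individual: tuple[int, int] = (1, 6),
    clones_per_individual: tuple[int, int] = (8, 24),
    pcr_replicates: int = 2,
    pcr_error_rate: float = 1e-4,
    pseudogene_fraction: float = 2.0 / 59.0,
    n_codons: int = 66,
    inter_locus_divergence: float = 0.10,
    seed: int | None = None,
) -> tuple[list[CloneRecord], SimulationTruth]:
    """Generate a clone library with known truth.

    Clone allocation guarantees, independent of PCR error, that every
    haplotype assigned to an individual is represented by at least three
    clones spread over at least two PCR replicates -- the configuration the
    validation rules were designed for.
    """
    if not (0.0 <= pcr_error_rate <= 1.0 and 0.0 <= pseudogene_fraction <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    lo_h, hi_h = haplotypes_per_individual
    lo_c, hi_c = clones_per_individual
    if lo_h < 1 or hi_h < lo_h or lo_c < 1 or hi_c < lo_c:
        raise ValueError("impossible haplotype/clone ranges")
    if pcr_replicates < 1:
        raise ValueError("need at least one PCR replicate")
    if 3 * hi_h > hi_c:
        raise ValueError(
            "clone budget too small: need clones_per_individual upper bound "
            ">= 3 * haplotypes_per_individual upper bound"
        )
    rng = np.random.default_rng(seed)
    partition = pbs_codons if pbs_codons is not None else gull_pbs_partition(n_codons)
    pbs_set = set(partition.pbs_codons)

    # Two divergent locus ancestors with fixed inter-locus differences.
    anc_a = _random_coding_sequence(n_codons, rng)
    anc_b = _mutate_allele(
        anc_a, max(1, int(round(inter_locus_divergence * 3 * n_codons))),
        pbs_set, 1.0, rng,
    )

    pool: dict[str, PoolAllele] = {}
    seen_seqs: set[str] = set()
    n_total = sum(alleles_per_locus)
    n_pseudo = int(round(pseudogene_fraction * n_total))
    flat_ids: list[str] = []
    for locus, (anc, n_alleles) in zip(
        ("DAB", "DBB"), zip((anc_a, anc_b), alleles_per_locus)
    ):
        for r in range(1, n_alleles + 1):
            hid = f"{locus}{r:02d}"
            for _ in range(200):
                steps = int(rng.integers(0, 7))
                seq = _mutate_allele(anc, steps, pbs_set, pbs_nonsyn_multiplier, rng)
                if seq not in seen_seqs:
                    break
            else:
                raise RuntimeError("could not generate a distinct allele")
            seen_seqs.add(seq)
            pool[hid] = PoolAllele(hid, seq, locus, False)
            flat_ids.append(hid)
    # convert a fraction of pool alleles to pseudogenes
    if n_pseudo > 0:
        pseudo_ids = rng.choice(flat_ids, size=n_pseudo, replace=False)
        for hid in pseudo_ids:
            old = pool[hid]
            for _ in range(50):
                seq = _inject_stop(old.seq, rng)
                if seq not in seen_seqs:
                    break
            seen_seqs.discard(old.seq)
            seen_seqs.add(seq)
            pool[hid] = PoolAllele(hid, seq, old.locus, True)

    # assign haplotypes and emit clones
    assignments: dict[str, frozenset[str]] = {}
    clones: list[CloneRecord] = []
    for ind_idx in range(1, n_individuals + 1):
        ind = f"ind{ind_idx:03d}"
        h = int(rng.integers(lo_h, hi_h + 1))
        hap_ids = tuple(rng.choice(flat_ids, size=h, replace=False))
        assignments[ind] = frozenset(str(x) for x in hap_ids)
        c = int(rng.integers(lo_c, hi_c + 1))
        c = max(c, 3 * h)  # guarantee >= 3 clones per haplotype
        # distribute clones over haplotypes as evenly as possible
        per_hap = [c // h + (1 if i < c % h else 0) for i in range(h)]
        clone_no = 0
        for hid, n_clones in zip(hap_ids, per_hap):
            base = pool[str(hid)].seq
            for rep in range(n_clones):
                clone_no += 1
                pcr = f"pcr{(rep % pcr_replicates) + 1}"
                seq = base
                if pcr_error_rate > 0:
                    arr = np.array(list(seq))
                    hits = np.where(rng.random(len(arr)) < pcr_error_rate)[0]
                    for pos in hits:
                        choices = [b for b in _BASES if b != arr[pos]]
                        arr[pos] = choices[int(rng.integers(0, 3))]
                    seq = "".join(arr)
                clones.append(
                    CloneRecord(
                        individual_id=ind,
                        pcr_id=pcr,
                        clone_id=f"clone{clone_no:03d}",
                        seq=seq,
                    )
                )
    truth = SimulationTruth(
        allele_pool=pool,
        individual_assignments=assignments,
        parameters={
            "seed": seed,
            "n_individuals": n_individuals,
            "alleles_per_locus": alleles_per_locus,
            "pbs_nonsyn_multiplier": pbs_nonsyn_multiplier,
            "pcr_error_rate": pcr_error_rate,
            "pseudogene_fraction": pseudogene_fraction,
            "pcr_replicates": pcr_replicates,
        },
    )
    return clones, truth


def simulate_coalescent_sample(
    n: int,
    L: int,
    theta0: float,
    theta1: float,
    tau: float,
    seed: int | None = None,
    id_prefix: str = "ind",
) -> CodonAlignment:
    """Coalescent sample under the sudden-expansion demography.

    Time runs backward in mutational units: a pair of lineages coalesces at
    hazard 1/theta1 until tau, 1/theta0 beyond, and each lineage mutates at
    rate 1/2, so a pair separated for time T carries Poisson(T) differences
    (equilibrium mean theta).  Mutations follow the infinite-sites model and
    are mapped to distinct positions among ``L`` sites.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if min(theta0, theta1, tau) < 0:
        raise ValueError("parameters must be non-negative")
    if L < 3 or L % 3 != 0:
        raise ValueError("L must be a positive multiple of 3")
    rng = np.random.default_rng(seed)

    lineages: list[set[int]] = [{i} for i in range(n)]
    open_lens = [0.0] * n
    branch_sets: list[set[int]] = []
    branch_lens: list[float] = []
    t = 0.0
    k = n
    while k > 1:
        pair_rate = k * (k - 1) / 2.0
        while True:
            theta = theta1 if t < tau else theta0
            if theta == 0:  # instant coalescence in this epoch
                wait = 0.0
                break
            wait = rng.exponential(theta / pair_rate)
            if t < tau and t + wait > tau:
                # crossing the epoch boundary: advance to tau and redraw
                for i in range(k):
                    open_lens[i] += tau - t
                t = tau
                continue
            break
        for i in range(k):
            open_lens[i] += wait
        t += wait
        i, j = (int(x) for x in rng.choice(k, size=2, replace=False))
        if i > j:
            i, j = j, i
        branch_sets.append(lineages[i])
        branch_lens.append(open_lens[i])
        branch_sets.append(lineages[j])
        branch_lens.append(open_lens[j])
        merged = lineages[i] | lineages[j]
        for idx in (j, i):
            lineages.pop(idx)
            open_lens.pop(idx)
        lineages.append(merged)
        open_lens.append(0.0)
        k -= 1

    lens = np.array(branch_lens)
    total_len = float(lens.sum())
    S = int(rng.poisson(total_len / 2.0))
    if S > L:
        raise ValueError(
            f"{S} mutations exceed {L} sites under infinite sites; increase L"
        )
    ancestral = "".join(_BASES[i] for i in rng.integers(0, 4, size=L))
    seqs = [list(ancestral) for _ in range(n)]
    if S > 0:
        positions = rng.choice(L, size=S, replace=False)
        probs = lens / total_len if total_len > 0 else np.full(lens.size, 1.0 / lens.size)
        which_branch = rng.choice(len(branch_sets), size=S, p=probs)
        for pos, b in zip(positions, which_branch):
            old = ancestral[pos]
            new = _BASES[(("ACGT".index(old)) + 1 + int(rng.integers(0, 3))) % 4]
            for leaf in branch_sets[b]:
                seqs[leaf][pos] = new
    records = [
        (f"{id_prefix}{i + 1:03d}", "".join(seqs[i])) for i in range(n)
    ]
    return make_alignment(records)
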