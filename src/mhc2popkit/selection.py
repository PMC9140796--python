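"""Codon-level selection statistics.

Two classic, complementary views of selection on a coding alignment:

* **Nei--Gojobori dN/dS.**  Counts synonymous and non-synonymous differences
  per codon with equal-weight averaging over all substitution pathways for
  multi-difference codons, divides by the potential synonymous /
  non-synonymous site counts, applies the Jukes--Cantor multiple-hit
  correction ``d = -(3/4) ln(1 - (4/3) p)``, and tests ``dN = dS`` with a
  Z-statistic whose variances come from a codon-resampling bootstrap.
  ``omega = dN/dS > 1`` over the peptide-binding codons is the signature of
  pathogen-driven diversifying selection on MHC.

* **Wu--Kabat variability.**  Per-residue score ``W = N * k / n`` (``N``
  sequences, ``k`` distinct residues, ``n`` copies of the commonest residue)
  flags hypervariable positions without any phylogenetic model; runs of
  invariant residues mark structurally constrained stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np
from scipy.stats import norm

from .seqio import CodonAlignment, PeptideSequence
from .diversity import SitePartition

_BASES = "TCAG"
_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}

# Standard genetic code laid out over the TCAG x TCAG x TCAG codon order.
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_STOP = "*"


def _translate_codon(idx: int) -> str:
    return _AA_TABLE[idx]


@lru_cache(maxsize=1)
def _site_table() -> np.ndarray:
    """Potential synonymous sites s(codon) for all 64 codons.

    At each codon position, s gains (number of synonymous single-base
    changes)/3.  Changes that create a stop codon count as non-synonymous,
    so s + n = 3 exactly for every sense codon.
    """
    s = np.zeros(64)
    for i, codon in enumerate(_CODONS):
        aa = _translate_codon(i)
        if aa == _STOP:
            s[i] = np.nan
            continue
        syn = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if _translate_codon(_CODON_INDEX[mutant]) == aa:
                    syn += 1.0
        s[i] = syn / 3.0
    return s


def _count_path(a: str, b: str, order: tuple[int, ...]) -> tuple[float, float, bool]:
    """(syn, nonsyn, passes_through_stop) for one substitution ordering."""
    syn = nonsyn = 0.0
    cur = a
    hit_stop = False
    for pos in order:
        nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
        aa_cur = _translate_codon(_CODON_INDEX[cur])
        aa_nxt = _translate_codon(_CODON_INDEX[nxt])
        if aa_nxt == _STOP or aa_cur == _STOP:
            hit_stop = True
            nonsyn += 1.0
        elif aa_cur == aa_nxt:
            syn += 1.0
        else:
            nonsyn += 1.0
        cur = nxt
    return syn, nonsyn, hit_stop


@lru_cache(maxsize=1)
def _pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """Pathway-averaged (synonymous, non-synonymous) differences, 64 x 64.

    For codon pairs differing at 2 or 3 positions every ordering of the
    changes is a pathway; pathways passing through a stop codon are dropped
    and the remainder reweighted.  If every pathway is blocked, all pathways
    are used (steps into/out of stops counted as non-synonymous), preserving
    syn + nonsyn = number of differing positions.
    """
    syn_t = np.zeros((64, 64))
    nonsyn_t = np.zeros((64, 64))
    for i, a in enumerate(_CODONS):
        for j, b in enumerate(_CODONS):
            diff_pos = tuple(p for p in range(3) if a[p] != b[p])
            if not diff_pos:
                continue
            clean: list[tuple[float, float]] = []
            blocked: list[tuple[float, float]] = []
            for order in permutations(diff_pos):
                s, n, hit = _count_path(a, b, order)
                (blocked if hit else clean).append((s, n))
            paths = clean if clean else blocked
            syn_t[i, j] = float(np.mean([p[0] for p in paths]))
            nonsyn_t[i, j] = float(np.mean([p[1] for p in paths]))
    return syn_t, nonsyn_t


def codon_pair_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences for one codon pair."""
    syn_t, nonsyn_t = _pair_tables()
    i, j = _CODON_INDEX[a.upper()], _CODON_INDEX[b.upper()]
    return float(syn_t[i, j]), float(nonsyn_t[i, j])


def potential_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) potential sites for one sense codon."""
    s = float(_site_table()[_CODON_INDEX[codon.upper()]])
    return s, 3.0 - s


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; undefined (nan) at saturation p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def _codon_matrix(aln: CodonAlignment) -> np.ndarray:
    n_codons = aln.codon_count
    mat = np.empty((aln.n, n_codons), dtype=int)
    for r, seq in enumerate(aln.seqs):
        for c in range(n_codons):
            codon = seq[3 * c : 3 * c + 3]
            idx = _CODON_INDEX.get(codon)
            if idx is None:
                raise ValueError(
                    f"ambiguous codon {codon!r} at codon {c + 1}; "
                    "dN/dS requires unambiguous sequences"
                )
            if _translate_codon(idx) == _STOP:
                raise ValueError(
                    f"stop codon {codon!r} at codon {c + 1}; "
                    "exclude pseudogenes before computing dN/dS"
                )
            mat[r, c] = idx
    return mat


@dataclass(frozen=True)
class NGResult:
    dN: float
    dN_se: float
    dS: float
    dS_se: float
    diff: float
    diff_se: float
    omega: float | None
    Z: float
    p_neq: float
    p_pos: float
    p_neg: float
    partition_label: str
    codons_used: int
    n_pairs: int
    n_saturated_pairs: int


def _dn_ds_from_codons(
    C: np.ndarray, codon_idx: np.ndarray, correction: str
) -> tuple[float, float, int]:
    """Mean dN, dS over all sequence pairs for the given codon columns.

    Returns (dN, dS, n_saturated) where saturated pairs (p >= 3/4 after
    averaging potential sites) are excluded from the means.
    """
    syn_t, nonsyn_t = _pair_tables()
    site_t = _site_table()
    sub = C[:, codon_idx]
    n = sub.shape[0]
    s_sites = site_t[sub].sum(axis=1)  # per sequence
    total_sites = 3.0 * sub.shape[1]
    dns, dss = [], []
    saturated = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            sd = syn_t[sub[i], sub[j]].sum()
            nd = nonsyn_t[sub[i], sub[j]].sum()
            S_bar = 0.5 * (s_sites[i] + s_sites[j])
            N_bar = total_sites - S_bar
            pS = sd / S_bar if S_bar > 0 else 0.0
            pN = nd / N_bar if N_bar > 0 else 0.0
            if correction == "jukes_cantor":
                dS_ij, dN_ij = jukes_cantor(pS), jukes_cantor(pN)
                if np.isnan(dS_ij) or np.isnan(dN_ij):
                    saturated += 1
                    continue
            else:
                dS_ij, dN_ij = pS, pN
            dss.append(dS_ij)
            dns.append(dN_ij)
    if not dns:
        raise ValueError("all sequence pairs saturated; distances undefined")
    return float(np.mean(dns)), float(np.mean(dss)), saturated


def ng_dn_ds(
    aln: CodonAlignment,
    partition: SitePartition | None = None,
    correction: str = "jukes_cantor",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> NGResult:
    """Nei--Gojobori dN/dS over a codon partition, with bootstrap Z-test.

    The Z statistic is ``(dN - dS) / sqrt(Var(dN) + Var(dS))`` with variances
    estimated by resampling codon columns (``bootstrap_reps`` replicates).
    ``p_neq`` is the two-tailed normal p-value; ``p_pos``/``p_neg`` are the
    one-tailed p-values for the diversifying (dN > dS) and purifying
    (dN < dS) alternatives.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    C = _codon_matrix(aln)
    codon_idx = (
        partition.codon_indices() if partition is not None else np.arange(aln.codon_count)
    )
    if codon_idx.size == 0:
        raise ValueError("empty partition")
    dN, dS, saturated = _dn_ds_from_codons(C, codon_idx, correction)

    rng = np.random.default_rng(seed)
    var_dN = var_dS = 0.0
    if bootstrap_reps > 0:
        reps_dN = np.empty(bootstrap_reps)
        reps_dS = np.empty(bootstrap_reps)
        for b in range(bootstrap_reps):
            resampled = rng.choice(codon_idx, size=codon_idx.size, replace=True)
            try:
                reps_dN[b], reps_dS[b], _ = _dn_ds_from_codons(C, resampled, correction)
            except ValueError:  # fully saturated resample
                reps_dN[b] = reps_dS[b] = np.nan
        var_dN = float(np.nanvar(reps_dN, ddof=1))
        var_dS = float(np.nanvar(reps_dS, ddof=1))

    diff = dN - dS
    total_var = var_dN + var_dS
    if total_var > 0:
        Z = diff / np.sqrt(total_var)
        p_neq = 2.0 * norm.sf(abs(Z))
        p_pos = float(norm.sf(Z))
        p_neg = float(norm.cdf(Z))
    else:
        Z = 0.0
        p_neq, p_pos, p_neg = 1.0, 0.5, 0.5
    omega = dN / dS if dS > 0 else None
    return NGResult(
        dN=dN, dN_se=float(np.sqrt(var_dN)), dS=dS, dS_se=float(np.sqrt(var_dS)),
        diff=diff, diff_se=float(np.sqrt(total_var)),
        omega=omega, Z=float(Z), p_neq=float(p_neq), p_pos=p_pos, p_neg=p_neg,
        partition_label=partition.label if partition is not None else "all",
        codons_used=int(codon_idx.size),
        n_pairs=aln.n * (aln.n - 1) // 2,
        n_saturated_pairs=saturated,
    )


def z_test_selection(
    dN: float, var_dN: float, dS: float, var_dS: float, alternative: str = "neq"
) -> tuple[float, float]:
    """Z-test of dN vs dS given externally estimated variances."""
    total = var_dN + var_dS
    if var_dN < 0 or var_dS < 0:
        raise ValueError("variances must be non-negative")
    if total == 0:
        raise ValueError("both variances are zero; Z undefined")
    Z = (dN - dS) / np.sqrt(total)
    if alternative == "neq":
        p = 2.0 * norm.sf(abs(Z))
    elif alternative == "pos":
        p = norm.sf(Z)
    elif alternative == "neg":
        p = norm.cdf(Z)
    else:
        raise ValueError(f"alternative must be neq/pos/neg, got {alternative!r}")
    return float(Z), float(p)


@dataclass(frozen=True)
class WuKabatProfile:
    W: np.ndarray
    mean_W: float
    polymorphic_sites: tuple[int, ...]  # 1-based codons with W > 2 * mean_W
    conserved_runs: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end)


def wu_kabat_profile(
    peptides: list[PeptideSequence], min_run: int = 6
) -> WuKabatProfile:
    """Wu--Kabat variability per residue plus conserved runs.

    ``W_i = N * k_i / n_i`` with ``N`` the sequence count, ``k_i`` the number
    of distinct residues and ``n_i`` the count of the commonest residue at
    position i ('X' ignored in both).  Invariant positions score exactly 1.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides")
    lengths = {len(p.aa) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides have unequal lengths")
    N = len(peptides)
    L = lengths.pop()
    mat = np.array([list(p.aa) for p in peptides], dtype="U1")
    W = np.empty(L)
    invariant = np.zeros(L, dtype=bool)
    for i in range(L):
        col = mat[:, i]
        col = col[col != "X"]
        if col.size == 0:
            W[i] = np.nan
            continue
        vals, counts = np.unique(col, return_counts=True)
        W[i] = N * len(vals) / counts.max()
        invariant[i] = len(vals) == 1
    mean_W = float(np.nanmean(W))
    poly = tuple(int(i + 1) for i in range(L) if W[i] > 2.0 * mean_W)
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(L + 1):
        if i < L and invariant[i]:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                runs.append((start + 1, i))
            start = None
    return WuKabatProfile(
        W=W, mean_W=mean_W, polymorphic_sites=poly, conserved_runs=tuple(runs)
    )
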