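"""Collapse clone libraries into haplotypes and classify them.

Cloning PCR products amplifies polymerase errors along with real alleles, so
raw clone sequences cannot be taken at face value.  The validation rules used
here are the conventional ones for clone-based MHC genotyping:

* a haplotype recovered from two or more individuals is a *putative true*
  allele (independent templates cannot share a PCR error);
* a haplotype seen in a single individual needs at least three identical
  clones to count as a *unique* allele;
* haplotypes must additionally be recovered from at least two independent
  PCR replicates;
* a haplotype whose translation carries an internal stop codon is a
  *pseudogene* (kept as a haplotype, excluded from coding-sequence
  statistics);
* anything else is an *artifact* and is discarded downstream.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .seqio import CloneRecord, has_internal_stop


class AlleleClass(str, Enum):
    PUTATIVE_TRUE = "putative_true"
    UNIQUE = "unique"
    PSEUDOGENE = "pseudogene"
    ARTIFACT = "artifact"


@dataclass(frozen=True)
class AlleleEntry:
    haplotype_id: str
    seq: str
    klass: AlleleClass
    carriers: frozenset[str]
    clone_count: int
    pcr_replicates: int


@dataclass(frozen=True)
class AlleleCatalog:
    entries: tuple[AlleleEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_class(self, klass: AlleleClass) -> list[AlleleEntry]:
        return [e for e in self.entries if e.klass is klass]

    def non_artifact(self) -> list[AlleleEntry]:
        return [e for e in self.entries if e.klass is not AlleleClass.ARTIFACT]

    def coding(self) -> list[AlleleEntry]:
        """Validated coding haplotypes: putative true + unique."""
        return [
            e
            for e in self.entries
            if e.klass in (AlleleClass.PUTATIVE_TRUE, AlleleClass.UNIQUE)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": [e.haplotype_id for e in self.entries],
                "class": [e.klass.value for e in self.entries],
                "carriers": [",".join(sorted(e.carriers)) for e in self.entries],
                "n_carriers": [len(e.carriers) for e in self.entries],
                "clone_count": [e.clone_count for e in self.entries],
                "pcr_replicates": [e.pcr_replicates for e in self.entries],
                "sequence": [e.seq for e in self.entries],
            }
        )


def classify_haplotypes(
    clones: Sequence[CloneRecord],
    min_individuals: int = 2,
    min_clones_unique: int = 3,
    min_pcr: int = 2,
    require_pcr_for_pseudogene: bool = True,
    id_prefix: str = "Hap",
) -> AlleleCatalog:
    """Collapse identical clone sequences to haplotypes and classify them.

    Identity is exact nucleotide identity -- no mismatch tolerance, matching
    the validation protocol this package models.  Classification precedence:
    a stop-bearing haplotype that satisfies either count rule is a pseudogene;
    otherwise >= ``min_individuals`` carriers (and >= ``min_pcr`` replicates)
    makes a putative true allele; a single-carrier haplotype needs
    >= ``min_clones_unique`` identical clones (and >= ``min_pcr`` replicates)
    to be a unique allele; everything else is an artifact.

    Haplotype IDs are assigned deterministically: rank by descending clone
    count, ties broken by sequence lexicographic order.
    """
    if not clones:
        return AlleleCatalog(())
    lengths = {len(c.seq) for c in clones}
    if len(lengths) != 1:
        raise ValueError(f"clone sequences have unequal lengths: {sorted(lengths)}")

    carriers: dict[str, set[str]] = defaultdict(set)
    pcrs: dict[str, set[tuple[str, str]]] = defaultdict(set)
    counts: Counter[str] = Counter()
    per_carrier_counts: dict[str, Counter[str]] = defaultdict(Counter)
    for c in clones:
        counts[c.seq] += 1
        carriers[c.seq].add(c.individual_id)
        # PCR replicates are counted per (individual, pcr) pair: two runs on
        # the same individual are independent verifications.
        pcrs[c.seq].add((c.individual_id, c.pcr_id))
        per_carrier_counts[c.seq][c.individual_id] += 1

    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    width = max(2, len(str(len(ordered))))
    entries: list[AlleleEntry] = []
    for rank, seq in enumerate(ordered, start=1):
        n_carriers = len(carriers[seq])
        # Independent PCRs = distinct (individual, pcr) reactions.
        n_pcr = len(pcrs[seq])
        clone_count = counts[seq]
        meets_true = n_carriers >= min_individuals and n_pcr >= min_pcr
        meets_unique = (
            n_carriers == 1
            and clone_count >= min_clones_unique
            and n_pcr >= min_pcr
        )
        stop = has_internal_stop(seq)
        if stop and (meets_true or meets_unique or not require_pcr_for_pseudogene):
            klass = AlleleClass.PSEUDOGENE
        elif not stop and meets_true:
            klass = AlleleClass.PUTATIVE_TRUE
        elif not stop and meets_unique:
            klass = AlleleClass.UNIQUE
        else:
            klass = AlleleClass.ARTIFACT
        entries.append(
            AlleleEntry(
                haplotype_id=f"{id_prefix}{rank:0{width}d}",
                seq=seq,
                klass=klass,
                carriers=frozenset(carriers[seq]),
                clone_count=clone_count,
                pcr_replicates=n_pcr,
            )
        )
    return AlleleCatalog(tuple(entries))


def summarize_catalog(cat: AlleleCatalog) -> dict:
    """Per-class counts and the haplotypes-per-individual histogram.

    The histogram covers non-artifact haplotypes only, mirroring how a
    genotyping study reports 'alleles per individual'.
    """
    class_counts = {k.value: 0 for k in AlleleClass}
    for e in cat.entries:
        class_counts[e.klass.value] += 1
    per_individual: Counter[str] = Counter()
    for e in cat.non_artifact():
        for ind in e.carriers:
            per_individual[ind] += 1
    histogram: Counter[int] = Counter(per_individual.values())
    return {
        "class_counts": class_counts,
        "haplotypes_per_individual": dict(sorted(histogram.items())),
        "n_individuals": len(per_individual),
    }
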