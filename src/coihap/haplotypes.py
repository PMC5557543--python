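"""Haplotype collapsing and the sufficient statistics for neutrality tests.

A haplotype is defined by exact full-length string identity. The
DiversitySummary gathers everything the site-frequency-spectrum statistics
need: segregating sites S, singleton mutations eta_s with their
per-sequence attribution U_i, mean pairwise differences k, nucleotide
diversity pi and haplotype diversity Hd.

Singleton rule (no outgroup available): at each segregating column the
majority base stands in for the ancestral state (ties broken
alphabetically); every non-majority base observed in exactly one sequence
is one singleton mutation, attributed to its carrier. At a strictly
biallelic column with counts (1, n-1) this reduces to "the minority base
is the singleton", matching the outgroup-free D*/F* convention. A column
with three bases each seen once therefore contributes two singletons while
S counts the column once, so eta_s can exceed S at multi-allelic columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seqio import ACGT, Alignment

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Unique sequences with their abundances and member sample ids."""

    haplotypes: list  # of (hap_id, seq, count, members)
    n_total: int
    excluded: list = field(default_factory=list)  # ids dropped for ambiguity

    def __len__(self):
        return len(self.haplotypes)

    @property
    def ids(self):
        return [h[0] for h in self.haplotypes]

    @property
    def seqs(self):
        return [h[1] for h in self.haplotypes]

    @property
    def counts(self):
        return [h[2] for h in self.haplotypes]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(h[0], h[2], ",".join(h[3]), h[1]) for h in self.haplotypes],
            columns=["hap_id", "count", "member_ids", "sequence"],
        )


@dataclass
class DiversitySummary:
    """Sufficient statistics of within-group sequence variation.

    Attributes
    ----------
    n : sequences used
    L_used : columns retained after the deletion policy
    S : segregating sites (columns with >=2 distinct bases)
    eta_s : total singleton mutations
    U : per-sequence singleton counts, length n
    k : mean pairwise nucleotide differences (per sequence pair)
    pi : k / L_used (per-site nucleotide diversity)
    Hd : haplotype diversity, n/(n-1) * (1 - sum p_h^2)
    """

    n: int
    L_used: int
    S: int
    eta_s: int
    U: np.ndarray
    k: float
    pi: float
    Hd: float
    deletion: str = "complete"


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Collapse an alignment to unique haplotypes by exact string equality.

    Sequences containing any character outside {A,C,G,T} are excluded from
    collapsing (their ids logged and reported on the table). The hap_id is
    the id of the first member encountered, in input order.
    """
    if not len(aln):
        raise ValueError("empty alignment")
    order: dict[str, int] = {}
    haps: list[list] = []  # [hap_id, seq, count, members]
    excluded = []
    for rec in aln:
        if set(rec.seq) - ACGT:
            excluded.append(rec.id)
            continue
        idx = order.get(rec.seq)
        if idx is None:
            order[rec.seq] = len(haps)
            haps.append([rec.id, rec.seq, 1, [rec.id]])
        else:
            haps[idx][2] += 1
            haps[idx][3].append(rec.id)
    if excluded:
        logger.warning(
            "%d sequences excluded from haplotype collapsing (ambiguous/gap "
            "characters): %s", len(excluded), ",".join(excluded),
        )
    if not haps:
        raise ValueError("all sequences excluded (none are pure A/C/G/T)")
    n_total = sum(h[2] for h in haps)
    return HaplotypeTable([tuple(h) for h in haps], n_total, excluded)


def _matrix(aln: Alignment) -> np.ndarray:
    return np.frombuffer(
        "".join(aln.sequences()).encode(), dtype="S1"
    ).reshape(len(aln), aln.length)


def diversity_summary(aln: Alignment, deletion: str = "complete") -> DiversitySummary:
    """Compute n, S, eta_s, U, k, pi and Hd for an alignment.

    Under ``complete`` deletion (default, required by the neutrality
    stages) every column containing a non-ACGT character in any sequence is
    removed before anything is computed. Under ``pairwise`` deletion k is
    averaged over per-pair comparable columns; S, eta_s and U are still
    computed on the complete-deletion column set so that Sigma U = eta_s
    remains well defined.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("diversity summary requires n >= 2 sequences")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")

    M = _matrix(aln)
    bases = np.array([b"A", b"C", b"G", b"T"])
    is_acgt = np.isin(M, bases)
    keep = is_acgt.all(axis=0)
    Mc = M[:, keep]
    L_used = Mc.shape[1]

    # per-column base counts over the complete-deletion set
    counts = np.stack([(Mc == b).sum(axis=0) for b in bases])  # 4 x L
    n_distinct = (counts > 0).sum(axis=0)
    seg = n_distinct >= 2
    S = int(seg.sum())

    # singleton attribution (majority base = ancestral proxy; alphabetical
    # tie-break via argmax over A<C<G<T ordering)
    U = np.zeros(n, dtype=int)
    eta_s = 0
    for c in np.nonzero(seg)[0]:
        col_counts = counts[:, c]
        major = int(np.argmax(col_counts))
        for b in range(4):
            if b != major and col_counts[b] == 1:
                carrier = int(np.nonzero(Mc[:, c] == bases[b])[0][0])
                U[carrier] += 1
                eta_s += 1

    # mean pairwise differences via per-column allele counts
    if deletion == "complete":
        pair_diffs = (counts * (n - counts)).sum() / 2.0
        k = pair_diffs / (n * (n - 1) / 2.0)
        pi = k / L_used if L_used else 0.0
    else:
        both = is_acgt.astype(np.int8)
        k_sum, npairs = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                comp = (both[i] & both[j]).astype(bool)
                if comp.any():
                    k_sum += float((M[i, comp] != M[j, comp]).sum())
                    npairs += 1
        k = k_sum / npairs if npairs else 0.0
        pi = k / aln.length

    table = collapse_haplotypes(aln)
    freqs = np.array(table.counts, dtype=float) / table.n_total
    Hd = table.n_total / (table.n_total - 1) * (1.0 - float((freqs**2).sum())) if table.n_total > 1 else 0.0

    return DiversitySummary(
        n=n, L_used=L_used, S=S, eta_s=int(eta_s), U=U,
        k=float(k), pi=float(pi), Hd=float(Hd), deletion=deletion,
    )


def write_haplotype_table(table: HaplotypeTable, tsv_path) -> None:
    table.to_frame().to_csv(tsv_path, sep="\t", index=False)


def haplotypes_to_alignment(table: HaplotypeTable) -> Alignment:
    """The unique-haplotype alignment feeding the network stage."""
    from .seqio import SequenceRecord

    return Alignment([SequenceRecord(h[0], h[1]) for h in table.haplotypes])
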