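"""McDonald-Kreitman test: polymorphism vs divergence, syn vs nonsyn.

Codon-aware classification under a configurable genetic code (default:
invertebrate mitochondrial, NCBI table 5, the right code for insect COI).
Within-group polymorphism and ingroup-vs-outgroup fixed differences are
classified synonymous/nonsynonymous per mutational step; codon states
differing at more than one position are resolved by averaging over all
minimal mutational pathways with equal weights (pathways through stop
codons are excluded when any stop-free pathway exists), which is why the
table holds fractional counts. Fisher's exact test (two-sided, on
round-half-to-even integerized counts) gives the p-value; the neutrality
index NI = (Pn/Ps)/(Dn/Ds) is reported when defined.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass

from Bio.Data import CodonTable
from scipy.stats import hypergeom

from .seqio import ACGT, Alignment

logger = logging.getLogger(__name__)

DEFAULT_CODE = 5  # invertebrate mitochondrial


@dataclass
class MKTable:
    poly_syn: float
    poly_non: float
    fix_syn: float
    fix_non: float
    p_two_sided: float | None = None

    @property
    def neutrality_index(self) -> float | None:
        if self.poly_syn > 0 and self.fix_syn > 0 and self.fix_non > 0:
            return (self.poly_non / self.poly_syn) / (self.fix_non / self.fix_syn)
        return None

    def to_dict(self) -> dict:
        return {
            "poly_syn": self.poly_syn,
            "poly_non": self.poly_non,
            "fix_syn": self.fix_syn,
            "fix_non": self.fix_non,
            "p_two_sided": self.p_two_sided,
            "neutrality_index": self.neutrality_index,
        }


def _code_table(code: int):
    table = CodonTable.unambiguous_dna_by_id[code]
    return table.forward_table, set(table.stop_codons)


def _pathway_counts(c1: str, c2: str, fwd: dict, stops: set) -> tuple[float, float]:
    """Average (syn, non) step counts over minimal pathways c1 -> c2."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and nxt != c2:
                ok = False
                break
            aa_cur = fwd.get(cur)
            aa_nxt = fwd.get(nxt)
            # a step into/out of a stop codon is nonsynonymous by convention
            steps.append("syn" if (aa_cur is not None and aa_cur == aa_nxt) else "non")
            cur = nxt
        if ok:
            pathways.append(steps)
    if not pathways:  # every route crosses a stop; fall back to all routes
        for order in itertools.permutations(diff):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                aa_cur, aa_nxt = fwd.get(cur), fwd.get(nxt)
                steps.append("syn" if (aa_cur is not None and aa_cur == aa_nxt) else "non")
                cur = nxt
            pathways.append(steps)
    syn = sum(s.count("syn") for s in pathways) / len(pathways)
    non = sum(s.count("non") for s in pathways) / len(pathways)
    return syn, non


def _codon_column(aln: Alignment, start: int) -> list[str]:
    """Pure-ACGT codons at [start, start+3) across sequences."""
    return [
        r.seq[start : start + 3]
        for r in aln
        if not (set(r.seq[start : start + 3]) - ACGT)
    ]


def _consensus_codon(codons: list[str]) -> str:
    return "".join(
        Counter(c[i] for c in codons).most_common(1)[0][0] for i in range(3)
    )


def classify_changes(
    ingroup: Alignment,
    outgroup: Alignment,
    frame_offset: int = 0,
    code: int = DEFAULT_CODE,
) -> MKTable:
    """Build the 2x2 MK table from two aligned sequence sets.

    Per codon: ingroup polymorphism contributes polymorphism counts (each
    non-majority ingroup codon vs the ingroup majority codon); codon
    positions fixed in the ingroup and different from the outgroup
    consensus contribute divergence counts. Positions polymorphic in both
    groups are excluded from divergence.
    """
    if ingroup.length != outgroup.length:
        raise ValueError("ingroup and outgroup alignments differ in length")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if ingroup.length - frame_offset < 3:
        raise ValueError("alignment too short for a single codon in this frame")
    fwd, stops = _code_table(code)

    # reading-frame sanity: no internal stop in the ingroup consensus
    n_codons = (ingroup.length - frame_offset) // 3
    for ci in range(n_codons):
        start = frame_offset + 3 * ci
        cods = _codon_column(ingroup, start)
        if cods and _consensus_codon(cods) in stops and ci < n_codons - 1:
            raise ValueError(
                f"internal stop codon at codon {ci + 1} in frame {frame_offset}; "
                "try another frame_offset"
            )

    ps = pn = ds = dn = 0.0
    for ci in range(n_codons):
        start = frame_offset + 3 * ci
        in_cods = _codon_column(ingroup, start)
        out_cods = _codon_column(outgroup, start)
        if not in_cods or not out_cods:
            logger.warning("codon %d skipped (no pure-ACGT codons)", ci + 1)
            continue
        in_counts = Counter(in_cods)
        in_major = _consensus_codon(in_cods)
        out_cons = _consensus_codon(out_cods)

        # polymorphism: each distinct non-majority ingroup codon vs majority
        for codon in sorted(in_counts):
            if codon == in_major:
                continue
            s, nsy = _pathway_counts(in_major, codon, fwd, stops)
            ps += s
            pn += nsy

        # divergence: restrict to positions fixed in the ingroup and not
        # polymorphic in both groups
        in_poly_pos = {
            i for i in range(3) if len({c[i] for c in in_cods}) > 1
        }
        out_poly_pos = {
            i for i in range(3) if len({c[i] for c in out_cods}) > 1
        }
        div_pos = [
            i
            for i in range(3)
            if i not in in_poly_pos
            and in_major[i] != out_cons[i]
            and not (i in in_poly_pos and i in out_poly_pos)
        ]
        if div_pos:
            target = "".join(
                out_cons[i] if i in div_pos else in_major[i] for i in range(3)
            )
            s, nsy = _pathway_counts(in_major, target, fwd, stops)
            ds += s
            dn += nsy

    return MKTable(poly_syn=ps, poly_non=pn, fix_syn=ds, fix_non=dn)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by hypergeometric summation.

    Sums P(tables with the observed margins) over all tables whose
    probability is <= that of the observed one (with a small relative
    tolerance for float ties). A zero margin returns p = 1 with a warning.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("fisher_exact_2x2 needs nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.warning("zero margin in 2x2 table; p = 1")
        return 1.0
    rv = hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return float(min(1.0, total))


def _round_half_even(x: float) -> int:
    return int(round(x))  # Python 3 banker's rounding


def mk_test(
    ingroup: Alignment,
    outgroup: Alignment,
    frame_offset: int = 0,
    code: int = DEFAULT_CODE,
) -> MKTable:
    """Classify changes and attach the Fisher two-sided p-value."""
    table = classify_changes(ingroup, outgroup, frame_offset, code)
    counts = [table.poly_syn, table.poly_non, table.fix_syn, table.fix_non]
    ints = [_round_half_even(x) for x in counts]
    if any(abs(i - x) > 1e-9 for i, x in zip(ints, counts)):
        logger.info(
            "fractional MK counts %s rounded half-to-even to %s", counts, ints
        )
    table.p_two_sided = fisher_exact_2x2([[ints[1], ints[0]], [ints[3], ints[2]]])
    return table


def detect_frame(aln: Alignment, code: int = DEFAULT_CODE) -> int:
    """Convenience: the frame offset whose consensus has no internal stop."""
    fwd, stops = _code_table(code)
    for off in (0, 1, 2):
        n_codons = (aln.length - off) // 3
        ok = True
        for ci in range(n_codons - 1):
            cods = _codon_column(aln, off + 3 * ci)
            if cods and _consensus_codon(cods) in stops:
                ok = False
                break
        if ok:
            logger.info("auto-detected reading frame offset %d", off)
            return off
    raise ValueError("no stop-free reading frame found")
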