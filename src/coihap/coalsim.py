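"""Neutral coalescent simulation and survey-scale synthetic data.

The simulator draws Kingman genealogies for a constant-size panmictic
population or one growing exponentially (looking back, N(t) = N0 e^{-g t},
so the pairwise coalescence rate at time t is inflated by e^{g t}; waiting
times come from the closed-form inverse of the cumulative rate, no
numerical integration). Mutations are dropped either as exactly S events
placed uniformly on total branch length (the fixed-S null used for
neutrality-test p-values) or as a Poisson(theta/2 x total length) draw.
Infinite sites: one alignment column per mutation.

``simulate_survey`` emulates a whitefly-style field survey: sites in
agro-ecological zones with Poisson adult abundance, per-host species
mixtures, and per-species haplotype pools — including an "invasive" pool
with a star topology (one dominant haplotype plus single-step satellites),
the signature of a recent demographic expansion.

Reproducibility: one global seed; each stage derives its own stream from a
fixed offset (genealogy +0, mutations +1, realization +2, survey +3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment, SequenceRecord

# Stream offsets from the global seed (kept < 2^31).
OFF_GENEALOGY, OFF_MUTATIONS, OFF_REALIZE, OFF_SURVEY = 0, 1, 2, 3


def _rng(seed: int, offset: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(int(seed) + offset))


@dataclass
class CoalescentParams:
    n: int
    mode: str = "fixed_S"  # fixed_S | fixed_theta
    S: int | None = None
    theta: float | None = None
    growth: float = 0.0  # exponential growth rate, coalescent-time units
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 tips")
        if self.mode == "fixed_S" and (self.S is None or self.S < 0):
            raise ValueError("fixed_S mode requires S >= 0")
        if self.mode == "fixed_theta" and (self.theta is None or self.theta <= 0):
            raise ValueError("fixed_theta mode requires theta > 0")
        if self.growth < 0:
            raise ValueError("growth must be >= 0")


@dataclass
class Genealogy:
    """A rooted binary coalescent tree in branch decomposition.

    ``branches`` is a list of (tip mask, length) pairs, one per non-root
    lineage (2n - 2 of them); ``events`` records the (child_a, child_b,
    time) merge history defining the topology.
    """

    n: int
    branches: list  # of (np.ndarray bool mask over tips, float length)
    events: list
    tmrca: float
    total_length: float


def _waiting_time(k: int, t0: float, g: float, rng) -> float:
    """Time to the next coalescence among k lineages, measured from t0."""
    rate = k * (k - 1) / 2.0
    E = rng.exponential()
    if g == 0.0:
        return E / rate
    # solve rate/g * (e^{g(t0+w)} - e^{g t0}) = E for w
    return math.log(math.exp(g * t0) + g * E / rate) / g - t0


def simulate_genealogy(p: CoalescentParams, rng=None) -> Genealogy:
    rng = rng if rng is not None else _rng(p.seed, OFF_GENEALOGY)
    n = p.n
    # lineages: (mask, birth_time, node_id)
    lineages = [(np.eye(n, dtype=bool)[i], 0.0, i) for i in range(n)]
    branches, events = [], []
    t = 0.0
    next_node = n
    k = n
    while k > 1:
        t += _waiting_time(k, t, p.growth, rng)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (mi, bi, ni), (mj, bj, nj) = lineages[i], lineages[j]
        branches.append((mi, t - bi))
        branches.append((mj, t - bj))
        events.append((ni, nj, t))
        merged = (mi | mj, t, next_node)
        next_node += 1
        lineages = [lineages[x] for x in range(k) if x not in (i, j)] + [merged]
        k -= 1
    total = float(sum(b[1] for b in branches))
    return Genealogy(n=n, branches=branches, events=events, tmrca=t, total_length=total)


def drop_mutations(gen: Genealogy, mode: str, value, seed=None, rng=None) -> np.ndarray:
    """Place mutations on the genealogy; returns a (sites x tips) bool matrix.

    fixed_S places exactly ``value`` mutations multinomially on branch
    lengths; fixed_theta draws Poisson(value/2 x total_length) mutations.
    """
    rng = rng if rng is not None else _rng(seed if seed is not None else 0, OFF_MUTATIONS)
    lengths = np.array([b[1] for b in gen.branches])
    if mode == "fixed_S":
        n_mut = int(value)
    elif mode == "fixed_theta":
        n_mut = int(rng.poisson(value / 2.0 * gen.total_length))
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    if n_mut == 0:
        return np.zeros((0, gen.n), dtype=bool)
    picks = rng.choice(len(lengths), size=n_mut, p=lengths / lengths.sum())
    return np.stack([gen.branches[b][0] for b in picks])


def simulate_sfs_matrix(p: CoalescentParams, rng_gene=None, rng_mut=None) -> np.ndarray:
    """Genealogy + mutations in one call; the fixed-S null workhorse."""
    g = simulate_genealogy(p, rng=rng_gene)
    value = p.S if p.mode == "fixed_S" else p.theta
    return drop_mutations(g, p.mode, value, seed=p.seed, rng=rng_mut)


# ---------------------------------------------------------------------------
# Sequence realization


def make_anchor(length: int = 504, seed: int = 20170815) -> str:
    """A synthetic COI-like anchor sequence: frame 0, no stops under the
    invertebrate mitochondrial code (stops TAA/TAG), deterministic."""
    rng = _rng(seed)
    bases = "ACGT"
    codons = []
    while len(codons) * 3 < length - length % 3:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c in ("TAA", "TAG"):
            continue
        codons.append(c)
    tail = "".join(bases[i] for i in rng.integers(0, 4, size=length % 3))
    return ("".join(codons) + tail)[:length]


def realize_sequences(
    matrix: np.ndarray, anchor: str, seed: int = 0, ids=None, rng=None
) -> Alignment:
    """Embed a binary mutation matrix into nucleotide space on an anchor.

    Each mutation gets a distinct uniformly chosen anchor position and a
    random different base; the Hamming structure of the output equals the
    binary matrix's.
    """
    rng = rng if rng is not None else _rng(seed, OFF_REALIZE)
    n_mut, n = (matrix.shape if matrix.size else (0, matrix.shape[1]))
    L = len(anchor)
    if n_mut > L:
        raise ValueError(f"{n_mut} mutations exceed anchor length {L}")
    positions = rng.choice(L, size=n_mut, replace=False) if n_mut else []
    seqs = [list(anchor) for _ in range(n)]
    for m, pos in enumerate(positions):
        ref = anchor[pos]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        for tip in np.nonzero(matrix[m])[0]:
            seqs[tip][pos] = alt
    ids = ids if ids is not None else [f"sim{i}" for i in range(n)]
    return Alignment([SequenceRecord(i, "".join(s)) for i, s in zip(ids, seqs)])


# ---------------------------------------------------------------------------
# Survey-scale synthetic data


@dataclass
class SpeciesPoolConfig:
    """How one species' haplotype pool is produced."""

    label: str
    n_pool: int = 40
    S: int = 20
    growth: float = 0.0
    star: bool = False  # star pool: dominant haplotype + 1-step satellites
    dominant_freq: float = 0.65
    n_satellites: int = 40
    anchor_shift: int = 0  # fixed differences from the base anchor


@dataclass
class SurveyConfig:
    """Study-shaped survey: zones x sites x hosts x species mixtures.

    Zone mean abundances default to the surveyed means for the two
    high-abundance zones (SU 30.56, GF 28.21 adults/plant) and a documented
    18 for SG (reported only as "> 17 adults per plant").
    """

    zone_means: dict = field(
        default_factory=lambda: {"SU": 30.56, "GF": 28.21, "SG": 18.0}
    )
    sites_per_zone: int = 18
    individuals_per_site: int = 16
    hosts: dict = field(
        default_factory=lambda: {"cassava": 0.8, "tomato": 0.2}
    )
    mixtures: dict = field(
        default_factory=lambda: {
            "cassava": {"SSA1-SG1": 0.7, "SSA1-SG2": 0.2, "MED": 0.1},
            "tomato": {"SSA1-SG1": 0.3, "SSA1-SG2": 0.2, "MED": 0.5},
        }
    )
    species: list = field(
        default_factory=lambda: [
            SpeciesPoolConfig("SSA1-SG1", star=True, growth=50.0, S=25, anchor_shift=0),
            SpeciesPoolConfig("SSA1-SG2", S=20, anchor_shift=30),
            SpeciesPoolConfig("MED", S=8, anchor_shift=60),
        ]
    )
    year: str = "2013"
    seed: int = 1

    def __post_init__(self):
        for host, mix in self.mixtures.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"species mixture for host {host!r} must sum to 1")
        for z, m in self.zone_means.items():
            if m <= 0:
                raise ValueError(f"zone mean for {z!r} must be > 0")


@dataclass
class SurveyDataset:
    alignment: Alignment
    metadata: pd.DataFrame  # indexed by sample id
    site_table: pd.DataFrame  # site, zone, host, count
    true_labels: dict  # sample id -> species label
    panel: "object"  # ReferencePanel of species anchors


def _species_anchor(base: str, shift: int, rng) -> str:
    """Derive a species anchor with ``shift`` fixed differences from base."""
    if shift == 0:
        return base
    s = list(base)
    for pos in rng.choice(len(base), size=shift, replace=False):
        s[pos] = "ACGT".replace(base[pos], "")[rng.integers(0, 3)]
    return "".join(s)


def _build_pool(cfg: SpeciesPoolConfig, anchor: str, rng) -> list[str]:
    if cfg.star:
        sats = []
        seen = {anchor}
        while len(sats) < cfg.n_satellites:
            pos = int(rng.integers(0, len(anchor)))
            alt = "ACGT".replace(anchor[pos], "")[rng.integers(0, 3)]
            s = anchor[:pos] + alt + anchor[pos + 1 :]
            if s not in seen:
                seen.add(s)
                sats.append(s)
        return [anchor] + sats
    p = CoalescentParams(n=cfg.n_pool, mode="fixed_S", S=cfg.S, growth=cfg.growth)
    gen = simulate_genealogy(p, rng=rng)
    mat = drop_mutations(gen, "fixed_S", cfg.S, rng=rng)
    aln = realize_sequences(mat, anchor, rng=rng)
    return aln.sequences()


def simulate_survey(cfg: SurveyConfig):
    """Generate a full synthetic survey: FASTA-able alignment + metadata.

    Deterministic given cfg.seed: same seed, byte-identical outputs.
    """
    from .species import ReferencePanel

    rng = _rng(cfg.seed, OFF_SURVEY)
    base = make_anchor()
    anchors, pools = {}, {}
    for sp in cfg.species:
        anchors[sp.label] = _species_anchor(base, sp.anchor_shift, rng)
        pools[sp.label] = _build_pool(sp, anchors[sp.label], rng)

    host_names = list(cfg.hosts)
    host_probs = np.array([cfg.hosts[h] for h in host_names], dtype=float)
    host_probs = host_probs / host_probs.sum()

    records, meta_rows, site_rows, truth = [], [], [], {}
    site_no = 0
    for zone, mean in cfg.zone_means.items():
        for _ in range(cfg.sites_per_zone):
            site_no += 1
            site = f"site{site_no:02d}"
            host = host_names[int(rng.choice(len(host_names), p=host_probs))]
            count = int(rng.poisson(mean))
            site_rows.append((site, zone, host, count))
            mix = cfg.mixtures[host]
            sp_names = list(mix)
            sp_probs = np.array([mix[s] for s in sp_names])
            for ind in range(cfg.individuals_per_site):
                sid = f"{site}_w{ind:02d}"
                label = sp_names[int(rng.choice(len(sp_names), p=sp_probs))]
                sp_cfg = next(s for s in cfg.species if s.label == label)
                pool = pools[label]
                if sp_cfg.star:
                    if rng.random() < sp_cfg.dominant_freq:
                        seq = pool[0]
                    else:
                        seq = pool[1 + int(rng.integers(0, len(pool) - 1))]
                else:
                    seq = pool[int(rng.integers(0, len(pool)))]
                records.append(SequenceRecord(sid, seq, {
                    "site": site, "host": host, "zone": zone,
                    "year": cfg.year, "count": str(count),
                }))
                meta_rows.append((sid, site, host, zone, cfg.year, count))
                truth[sid] = label

    metadata = pd.DataFrame(
        meta_rows, columns=["id", "site", "host", "zone", "year", "count"]
    ).set_index("id")
    site_table = pd.DataFrame(site_rows, columns=["site", "zone", "host", "count"])
    panel = ReferencePanel(
        [(f"SYN_{sp.label}", sp.label, anchors[sp.label]) for sp in cfg.species]
    )
    return SurveyDataset(
        alignment=Alignment(records),
        metadata=metadata,
        site_table=site_table,
        true_labels=truth,
        panel=panel,
    )
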