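"""End-to-end orchestration: ingest -> collapse -> assign -> network ->
per-group neutrality -> MK -> survey GLM -> report bundle.

Every run writes a machine-readable manifest (input hashes, package
version, seed) so identical config + seed reproduces identical outputs.
Stage errors abort with the stage name; partial outputs keep a
``.partial`` suffix. Output tables declare their denominator and deletion
policy in a header comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .haplotypes import (
    collapse_haplotypes,
    diversity_summary,
    haplotypes_to_alignment,
    write_haplotype_table,
)
from .mk import detect_frame, mk_test
from .network import (
    annotate_groups,
    goeburst_mst,
    group_min_steps,
    group_mst_path_steps,
    hamming_matrix,
    k2p_matrix,
    neighbor_joining,
    write_dot,
    write_graphml,
)
from .neutrality import neutrality_suite
from .seqio import Alignment, read_fasta, read_metadata, write_fasta
from .species import (
    DEFAULT_SPECIES_THRESHOLD,
    DEFAULT_STRAND_THRESHOLD,
    ReferencePanel,
    assign_species,
    calls_to_frame,
    composition_tables,
)
from .survey import zone_abundance_analysis

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    alignment: str
    panel: str | None = None
    metadata: str | None = None
    outdir: str = "coihap_out"
    deletion: str = "complete"
    species_threshold: float = DEFAULT_SPECIES_THRESHOLD
    strand_threshold: float = DEFAULT_STRAND_THRESHOLD
    neutrality_reps: int = 10000
    seed: int = 1
    groups: list = field(default_factory=list)  # labels to run neutrality on
    min_group_n: int = 10
    mk_ingroup: str | None = None
    mk_outgroup: str | None = None
    frame_offset: int | None = None
    genetic_code: int = 5

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config with optional [section] headers (sections
        are cosmetic; keys are globally unique)."""
        values = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith(("#", ";", "[")):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        kwargs = {}
        for f_name, f_type in (
            ("alignment", str), ("panel", str), ("metadata", str),
            ("outdir", str), ("deletion", str),
            ("species_threshold", float), ("strand_threshold", float),
            ("neutrality_reps", int), ("seed", int), ("min_group_n", int),
            ("mk_ingroup", str), ("mk_outgroup", str),
            ("frame_offset", int), ("genetic_code", int),
        ):
            if f_name in values:
                kwargs[f_name] = f_type(values[f_name])
        if "groups" in values:
            kwargs["groups"] = [g.strip() for g in values["groups"].split(",") if g.strip()]
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_table(df, path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "deletion": cfg.deletion,
        "inputs": {},
        "outputs": [],
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
                manifest["stages"][name] = "ok"
                return result
            except Exception as exc:  # noqa: BLE001 — report stage + cause
                manifest["stages"][name] = f"failed: {exc}"
                _finalize(partial=True)
                raise StageError(name, exc) from exc

        return deco

    def _finalize(partial=False):
        name = "manifest.json.partial" if partial else "manifest.json"
        (out / name).write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # --- ingest
    @stage("ingest")
    def aln() -> Alignment:
        manifest["inputs"]["alignment"] = _sha256(cfg.alignment)
        meta = None
        if cfg.metadata:
            manifest["inputs"]["metadata"] = _sha256(cfg.metadata)
            meta = read_metadata(cfg.metadata)
        return read_fasta(cfg.alignment, metadata=meta)

    # --- collapse
    @stage("collapse")
    def table():
        t = collapse_haplotypes(aln)
        write_haplotype_table(t, out / "haplotypes.tsv")
        write_fasta(haplotypes_to_alignment(t), out / "haplotypes.fasta")
        manifest["outputs"] += ["haplotypes.tsv", "haplotypes.fasta"]
        manifest["n_sequences"] = t.n_total
        manifest["n_haplotypes"] = len(t)
        return t

    # --- species assignment
    calls = None
    groups_by_sample: dict = {}
    if cfg.panel:

        @stage("assign")
        def calls():
            manifest["inputs"]["panel"] = _sha256(cfg.panel)
            panel = ReferencePanel.from_fasta(cfg.panel)
            cs = assign_species(
                aln, panel, cfg.species_threshold, cfg.strand_threshold
            )
            _write_table(
                calls_to_frame(cs), out / "species_calls.tsv",
                f"denominator: {len(cs)} sequences; thresholds "
                f"{cfg.species_threshold}/{cfg.strand_threshold}",
            )
            manifest["outputs"].append("species_calls.tsv")
            return cs

        groups_by_sample = {c.sample_id: c.best_label for c in calls}

        if cfg.metadata:

            @stage("composition")
            def _comp():
                meta = read_metadata(cfg.metadata)
                for stratum, df in composition_tables(calls, meta).items():
                    _write_table(
                        df, out / f"composition_by_{stratum}.tsv",
                        f"denominator: per-{stratum} row counts of "
                        f"{len(calls)} calls",
                    )
                    manifest["outputs"].append(f"composition_by_{stratum}.tsv")

    # --- network
    @stage("network")
    def _network():
        dm = hamming_matrix(table)
        G = goeburst_mst(table, dm)
        hap_groups = {
            hid: groups_by_sample.get(hid, "unassigned") for hid in table.ids
        }
        annotate_groups(G, hap_groups)
        write_graphml(G, out / "network.graphml")
        write_dot(G, out / "network.dot")
        manifest["outputs"] += ["network.graphml", "network.dot"]
        if groups_by_sample:
            steps = group_min_steps(dm, hap_groups)
            path_steps = group_mst_path_steps(G, hap_groups)
            rows = [
                {"group1": g1, "group2": g2, "min_hamming": v,
                 "mst_path": path_steps.get((g1, g2), 0.0)}
                for (g1, g2), v in sorted(steps.items()) if g1 < g2
            ]
            import pandas as pd

            _write_table(
                pd.DataFrame(rows), out / "group_steps.tsv",
                "mutational steps: min pairwise Hamming (primary) and MST path",
            )
            manifest["outputs"].append("group_steps.tsv")

    # --- NJ tree
    @stage("tree")
    def _tree():
        if len(table) >= 3:
            dm = k2p_matrix(table.ids, table.seqs)
            tree = neighbor_joining(dm)
            (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
            manifest["outputs"].append("nj_tree.nwk")

    # --- per-group neutrality
    @stage("neutrality")
    def _neutrality():
        targets = cfg.groups or sorted(set(groups_by_sample.values()))
        results = {}
        for gi, label in enumerate(targets):
            members = [
                r for r in aln if groups_by_sample.get(r.id) == label
            ] if groups_by_sample else list(aln)
            if len(members) < max(4, cfg.min_group_n):
                logger.info("group %r too small (n=%d); skipped", label, len(members))
                continue
            sub = Alignment(members)
            ds = diversity_summary(sub, deletion=cfg.deletion)
            if ds.S < 1:
                logger.info("group %r has no variation; skipped", label)
                continue
            suite = neutrality_suite(
                ds, reps=cfg.neutrality_reps, seed=cfg.seed + 100 + gi
            )
            results[label] = {
                "n": ds.n, "S": ds.S, "eta_s": ds.eta_s, "k": ds.k,
                "pi": ds.pi, "Hd": ds.Hd, "L_used": ds.L_used,
                "deletion": ds.deletion,
                "tests": [r.to_dict() for r in suite],
            }
        (out / "neutrality.json").write_text(json.dumps(results, indent=2))
        manifest["outputs"].append("neutrality.json")
        return results

    # --- MK test
    if cfg.mk_ingroup and cfg.mk_outgroup and groups_by_sample:

        @stage("mktest")
        def _mk():
            ing = Alignment(
                [r for r in aln if groups_by_sample.get(r.id) == cfg.mk_ingroup]
            )
            outg = Alignment(
                [r for r in aln if groups_by_sample.get(r.id) == cfg.mk_outgroup]
            )
            frame = (
                cfg.frame_offset
                if cfg.frame_offset is not None
                else detect_frame(ing, cfg.genetic_code)
            )
            mkt = mk_test(ing, outg, frame, cfg.genetic_code)
            (out / "mk_test.json").write_text(json.dumps({
                "ingroup": cfg.mk_ingroup, "outgroup": cfg.mk_outgroup,
                "frame_offset": frame, "genetic_code": cfg.genetic_code,
                **mkt.to_dict(),
            }, indent=2))
            manifest["outputs"].append("mk_test.json")

    # --- survey GLM
    if cfg.metadata:
        meta = read_metadata(cfg.metadata)
        if "count" in meta.columns and "zone" in meta.columns:

            @stage("glm")
            def _glm():
                site_tbl = (
                    meta.reset_index()[["site", "zone", "count"]]
                    .drop_duplicates("site")
                    .astype({"count": int})
                )
                res = zone_abundance_analysis(site_tbl)
                (out / "glm_summary.json").write_text(json.dumps({
                    "rates": res["fit"].rates,
                    "dispersion": res["fit"].dispersion,
                    "test": res["test"],
                    "letters": res["letters"],
                    "denominator": f"{len(site_tbl)} sites (one count per site)",
                }, indent=2))
                manifest["outputs"].append("glm_summary.json")
        else:
            logger.info("no zone/count columns in metadata; survey stage skipped")
            manifest["stages"]["glm"] = "skipped: no zone/count columns"
    else:
        manifest["stages"]["glm"] = "skipped: no metadata"

    _finalize()
    return manifest


# ---------------------------------------------------------------------------
# Fixture generation


def make_fixtures(outdir, seed: int = 1) -> Path:
    """Write the test fixture family: F1, the star-expansion alignment, an
    additive-tree distance matrix, the MK codon fixture, and the default
    synthetic survey. F1 and the MK fixture are static; the survey and star
    depend on the seed."""
    from .coalsim import SurveyConfig, make_anchor, simulate_survey, _rng
    from .seqio import SequenceRecord, write_metadata

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # F1: the hand-enumerated diversity fixture (static)
    f1 = ["ACGTACGT", "ACGTACGA", "ACGAACGT", "ACGTACGT"]
    with open(out / "F1.fasta", "w") as fh:
        for i, s in enumerate(f1, 1):
            fh.write(f">s{i}\n{s}\n")

    # star expansion alignment: dominant haplotype + single-step satellites
    rng = _rng(seed, 7)
    anchor = make_anchor(length=120)
    records = [SequenceRecord(f"hub{i}", anchor) for i in range(30)]
    for i in range(10):
        pos = int(rng.integers(0, len(anchor)))
        alt = "ACGT".replace(anchor[pos], "")[rng.integers(0, 3)]
        records.append(
            SequenceRecord(f"sat{i}", anchor[:pos] + alt + anchor[pos + 1 :])
        )
    write_fasta(Alignment(records), out / "star.fasta")

    # additive 5-taxon distance fixture (caterpillar tree, exact distances)
    (out / "additive5.tsv").write_text(
        "\tA\tB\tC\tD\tE\n"
        "A\t0\t5\t9\t12\t13\n"
        "B\t5\t0\t10\t13\t14\n"
        "C\t9\t10\t0\t7\t8\n"
        "D\t12\t13\t7\t0\t5\n"
        "E\t13\t14\t8\t5\t0\n"
    )

    # MK fixture: 4 ingroup + 2 outgroup sequences, 4 codons (static)
    ing = ["ATGGCTAAAGGA", "ATGGCTAAAGGG", "ATGGCTAAAGGA", "ATGGCTAAAGGA"]
    outg = ["ATGGCTCGAGGA", "ATGGCTCGAGGA"]
    with open(out / "mk_ingroup.fasta", "w") as fh:
        for i, s in enumerate(ing, 1):
            fh.write(f">in{i}\n{s}\n")
    with open(out / "mk_outgroup.fasta", "w") as fh:
        for i, s in enumerate(outg, 1):
            fh.write(f">out{i}\n{s}\n")

    # default synthetic survey
    survey = simulate_survey(SurveyConfig(seed=seed))
    write_fasta(survey.alignment, out / "survey.fasta")
    write_metadata(survey.alignment, out / "survey_metadata.tsv")
    survey.panel.to_fasta(out / "survey_panel.fasta")
    return out
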