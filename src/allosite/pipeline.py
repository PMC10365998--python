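"""Stage orchestration: simulate -> screen -> scan -> logo -> tree -> superpose.

A :class:`PipelineConfig` (plain key=value file or dict) selects stages and
overrides; :func:`run_pipeline` executes them in dependency order into an
output directory, echoes the config verbatim, and writes a manifest listing
every artifact with its SHA-256 content hash. Identical config + seed gives
byte-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields
from typing import Dict, List, Optional

from . import logo as logo_mod
from . import motif as motif_mod
from . import phylogeny as phylo_mod
from . import screen as screen_mod
from . import superpose as superpose_mod
from . import synthetic as synth_mod
from .structure_io import read_structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # stage toggles
    simulate_structures: bool = True
    simulate_sequences: bool = True
    run_screen: bool = True
    run_scan: bool = True
    run_logo: bool = True
    run_tree: bool = True
    run_superpose: bool = True
    # inputs (used when the corresponding simulate stage is off)
    structures_dir: Optional[str] = None
    sequences_fasta: Optional[str] = None
    reference_fasta: Optional[str] = None
    # parameters
    n_structures: int = 12
    n_sequences: int = 60
    motif_prevalence: float = 0.75
    min_identity: float = 60.0
    fungal_variant: bool = False
    flank: int = 3
    n_tree_taxa: int = 12
    cutoff_aromatic: float = 5.0
    cutoff_arg: float = 5.0
    screen_mode: str = "full"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a key=value config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes", "on")
                elif isinstance(default, int):
                    kwargs[key] = int(val)
                elif isinstance(default, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val or None
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(outdir, exist_ok=True)
    artifacts: Dict[str, str] = {}
    timings: Dict[str, float] = {}

    # echo config verbatim
    cfg_path = os.path.join(outdir, "config.json")
    with open(cfg_path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
    artifacts["config"] = cfg_path

    # fail early on missing inputs
    if config.run_screen and not config.simulate_structures:
        if not config.structures_dir or not os.path.isdir(config.structures_dir):
            raise FileNotFoundError("screen stage: structures_dir missing")
    if config.run_scan and not config.simulate_sequences:
        if not config.sequences_fasta or not os.path.exists(config.sequences_fasta):
            raise FileNotFoundError("scan stage: sequences_fasta missing")

    def stage(name):
        def deco(fn):
            t0 = time.time()
            logger.info("stage %s: start", name)
            fn()
            timings[name] = round(time.time() - t0, 3)
            logger.info("stage %s: done in %.2fs", name, timings[name])
        return deco

    structure_paths: List[str] = []
    spec = motif_mod.MotifSpec(fungal_variant=config.fungal_variant)
    records = None
    reference = None

    if config.simulate_structures:
        @stage("simulate_structures")
        def _():
            nonlocal structure_paths
            sdir = os.path.join(outdir, "structures")
            labels = synth_mod.make_structure_library(config.n_structures, sdir,
                                                      seed=config.seed)
            lp = os.path.join(outdir, "structure_labels.tsv")
            labels.to_csv(lp, sep="\t", index=False)
            artifacts["structure_labels"] = lp
            structure_paths = sorted(os.path.join(sdir, p) for p in labels["pdb"])
    elif config.structures_dir:
        structure_paths = sorted(
            os.path.join(config.structures_dir, f)
            for f in os.listdir(config.structures_dir)
            if f.lower().endswith((".pdb", ".ent", ".cif", ".mmcif"))
        )

    if config.simulate_sequences:
        @stage("simulate_sequences")
        def _():
            nonlocal records, reference
            design = synth_mod.FamilyDesign(
                n_sequences=config.n_sequences,
                motif_prevalence=config.motif_prevalence,
                seed=config.seed,
            )
            records, _labels, reference = synth_mod.make_sequence_family(design, spec)
            fp = os.path.join(outdir, "family.fasta")
            synth_mod.write_fasta(records, fp)
            artifacts["family_fasta"] = fp
            lp = os.path.join(outdir, "sequence_labels.tsv")
            _labels.to_csv(lp, sep="\t", index=False)
            artifacts["sequence_labels"] = lp
    elif config.sequences_fasta:
        records = motif_mod.read_fasta(config.sequences_fasta)
        if config.reference_fasta:
            reference = motif_mod.read_fasta(config.reference_fasta)[0][1]
        else:
            reference = records[0][1]

    if config.run_screen and structure_paths:
        @stage("screen")
        def _():
            criteria = screen_mod.ScreenCriteria(
                d_aromatic=config.cutoff_aromatic, d_arg=config.cutoff_arg
            )
            hits = screen_mod.screen_library(structure_paths, criteria,
                                             mode=config.screen_mode)
            hp = os.path.join(outdir, "hits.tsv")
            hits.to_tsv(hp)
            artifacts["hit_table"] = hp
            sp = os.path.join(outdir, "screen_summary.json")
            with open(sp, "w") as fh:
                fh.write(hits.summary_json())
            artifacts["screen_summary"] = sp

    survey = None
    if config.run_scan and records is not None:
        @stage("scan")
        def _():
            nonlocal survey
            survey = motif_mod.motif_survey(records, reference,
                                            min_identity=config.min_identity, spec=spec)
            sp = os.path.join(outdir, "survey.tsv")
            survey.to_tsv(sp)
            artifacts["survey"] = sp
            pos = {r for r in survey.table.loc[survey.table.motif_present, "sequence_id"]}
            fp = os.path.join(outdir, "motif_positive.fasta")
            synth_mod.write_fasta([r for r in records if r[0] in pos], fp)
            artifacts["motif_positive_fasta"] = fp

    if config.run_logo and survey is not None and survey.n_motif > 0:
        @stage("logo")
        def _():
            seq_by_id = dict(records)
            matches = []
            for _, row in survey.table[survey.table.motif_present].iterrows():
                seq = seq_by_id[row.sequence_id]
                m = motif_mod.scan_sequence(seq, spec, sequence_id=row.sequence_id)[0]
                matches.append((m, seq))
            pfm = logo_mod.anchor_windows(matches, flank=config.flank, spec=spec)
            lp = os.path.join(outdir, "logo.json")
            with open(lp, "w") as fh:
                fh.write(pfm.to_json())
            artifacts["logo"] = lp

    if config.run_tree and survey is not None and survey.n_motif >= 3:
        @stage("tree")
        def _():
            seq_by_id = dict(records)
            pos_ids = survey.table.loc[survey.table.motif_present, "sequence_id"]
            taxa = list(pos_ids)[: config.n_tree_taxa]
            seqs = [seq_by_id[t] for t in taxa]
            D = phylo_mod.p_distance_matrix(seqs)
            tree = phylo_mod.neighbor_joining(D, taxa)
            tp = os.path.join(outdir, "tree.nwk")
            phylo_mod.write_newick(tree, tp)
            artifacts["tree"] = tp
            mp = os.path.join(outdir, "distances.phy")
            phylo_mod.write_phylip_matrix(D, taxa, mp)
            artifacts["distance_matrix"] = mp

    if config.run_superpose and len(structure_paths) >= 2:
        @stage("superpose")
        def _():
            ref = read_structure(structure_paths[0])
            mob = read_structure(structure_paths[1])
            try:
                result = superpose_mod.superpose_models(ref, mob)
            except superpose_mod.InsufficientCorrespondenceError as exc:
                logger.warning("superpose skipped: %s", exc)
                return
            sp = os.path.join(outdir, "superposition.json")
            with open(sp, "w") as fh:
                json.dump({"rotation": result.rotation.tolist(),
                           "translation": result.translation.tolist(),
                           "n_pairs": result.n_pairs,
                           "rmsd": round(result.rmsd, 6)}, fh, indent=2)
            artifacts["superposition"] = sp

    logger.info("stage timings: %s", timings)
    # timings go to the log, not the manifest, so identical config + seed
    # reruns produce byte-identical manifests
    manifest = {
        "config": asdict(config),
        "artifacts": {
            name: {"path": os.path.relpath(p, outdir), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    mp = os.path.join(outdir, "manifest.json")
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
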