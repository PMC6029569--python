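"""End-to-end orchestration: simulate (or load) -> map -> classify ->
standardize -> group -> QC -> summary, driven by a single config mapping.

Every stochastic stage derives its seed from the master seed, so re-running
with the same config is bit-identical; a manifest records inputs, seeds,
thresholds, per-genome decision traces and output hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import coverage as covmod
from . import genes as genemod
from . import grouping, qc, seqio, simulate, standardize
from .errors import ParameterError, PipelineError
from .types import GenomeRecord, PackagingStrategy, PatternLabel

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "mode": "simulate",
    "seed": 7,
    "strategies": [s.value for s in simulate.PackagingStrategy if s.value != "unknown"],
    "genomes_per_strategy": 1,
    "length": 40_000,
    "gc": 0.43,
    "depth": 50.0,
    "error_rate": 0.0,
    "n_virions": 50,
    "out_dir": None,
}


def _stage(stage: str, genome_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage!r} failed for genome {genome_id!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config) -> dict:
    """Run the full pipeline; returns an artifacts dict (and writes files if
    ``out_dir`` is configured).

    ``config`` is a mapping or a YAML path.  Simulate mode generates one or
    more genomes per packaging strategy with ground truth; real mode expects
    ``contigs`` (FASTA) plus ``reads`` (interleaved FASTQ) or ``coverage``
    (bedGraph) inputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}

    if cfg["mode"] == "simulate":
        genomes = _simulate_inputs(cfg)
    elif cfg["mode"] == "real":
        genomes = _load_inputs(cfg)
    else:
        raise ParameterError(f"unknown pipeline mode {cfg['mode']!r}")

    # per-genome evidence
    for g in genomes:
        gid = g["id"]
        with _stage("coverage", gid):
            placements, stats = covmod.map_reads(
                g["reads"], g["contig"], circular=g["contig"].circular_hint
            )
            profile = covmod.per_base_coverage(
                placements, len(g["contig"]), circular=g["contig"].circular_hint
            )
            g["profile"] = profile
            g["mapping_stats"] = stats
        with _stage("classify", gid):
            g["pattern"] = covmod.classify_pattern(profile)
        with _stage("genes", gid):
            g["orfs"] = genemod.find_orfs(g["contig"], circular=g["contig"].circular_hint)
        with _stage("terminase", gid):
            g["terminase"] = genemod.assign_terminase(g["orfs"]) if g["orfs"] else None
        with _stage("itr", gid):
            g["itr"] = (
                standardize.detect_itr(g["contig"])
                if not g["contig"].circular_hint
                else None
            )

    # grouping on proteomes
    proteomes = {g["id"]: [o.protein for o in g["orfs"]] for g in genomes}
    if len(proteomes) >= 2:
        clusters = grouping.reciprocal_best_hits(proteomes)
        groups = grouping.group_genomes(clusters)
        partner_pairs = grouping.identical_proteome_pairs(clusters)
    else:
        clusters, partner_pairs = [], []
        groups = [grouping.GenomeGroup(0, frozenset(proteomes))]
    partners: dict[str, set[str]] = {}
    for a, b in partner_pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    by_id = {g["id"]: g for g in genomes}
    plans = {}
    for group in groups:
        members = sorted(group.members)
        group_plans = standardize.select_strategy(
            members,
            {m: by_id[m]["terminase"] for m in members},
            {m: by_id[m]["pattern"] for m in members},
            itr_lengths={m: by_id[m]["itr"] for m in members},
            identical_protein_partners=partners,
        )
        plans.update(group_plans)

    standardized = {}
    for g in genomes:
        gid = g["id"]
        plan = plans[gid]
        with _stage("standardize", gid):
            standardized[gid] = _apply_plan(g, plan, standardized)

    artifacts = {
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "genomes": genomes,
        "groups": groups,
        "plans": plans,
        "standardized": standardized,
        "manifest": _manifest(cfg, genomes, plans, standardized),
    }
    if cfg.get("out_dir"):
        _write_outputs(Path(cfg["out_dir"]), artifacts)
    return artifacts


def _apply_plan(g, plan, standardized):
    contig = g["contig"]
    if plan.strategy == "relinearize_at_terl_upstream_orf":
        return standardize.relinearize_at_terl_upstream_orf(contig, g["orfs"], g["terminase"])
    if plan.strategy == "cut_at_coverage_feature":
        return standardize.cut_at_coverage_feature(contig, g["pattern"])
    if plan.strategy == "trim_mu_ends":
        return standardize.trim_mu_ends(contig, profile=g["profile"])
    if plan.strategy == "select_itr_contig":
        chosen = standardize.select_itr_contig(g.get("candidates", [contig]))
        out = standardize.maintain_original(chosen, reason="ITR contig selected")
        out.plan = plan
        return out
    if plan.strategy == "scaffold_to_reference":
        ref = standardized.get(plan.reference_id)
        if ref is None:
            raise PipelineError(f"scaffold reference {plan.reference_id} not yet standardized")
        return standardize.scaffold_to_reference(contig, ref)
    return standardize.maintain_original(contig, reason=plan.rationale.get("reason", ""))


def _simulate_inputs(cfg) -> list[dict]:
    rng = np.random.default_rng(cfg["seed"])
    host = GenomeRecord(
        "sim_host",
        "".join(np.random.default_rng(cfg["seed"] + 999_983).choice(
            list("ACGT"), size=60_000)),
    )
    genomes = []
    idx = 0
    for strat_name in cfg["strategies"]:
        strategy = PackagingStrategy(strat_name)
        for rep in range(cfg["genomes_per_strategy"]):
            gid = f"{strategy.value}_{rep}"
            seed = int(cfg["seed"] * 10_000 + idx)
            idx += 1
            with _stage("simulate", gid):
                g = simulate_genome_with_reads(
                    strategy,
                    length=cfg["length"],
                    gc=cfg["gc"],
                    depth=cfg["depth"],
                    error_rate=cfg["error_rate"],
                    n_virions=cfg["n_virions"],
                    seed=seed,
                    host=host,
                )
            g["id"] = gid
            g["contig"].id = gid
            genomes.append(g)
    return genomes


def simulate_genome_with_reads(
    strategy: PackagingStrategy,
    length: int = 40_000,
    gc: float = 0.43,
    depth: float = 50.0,
    error_rate: float = 0.0,
    n_virions: int = 50,
    seed: int = 0,
    host: GenomeRecord | None = None,
    params: simulate.PackagingParams | None = None,
) -> dict:
    """Simulate one genome under ``strategy`` through to reads + draft contig.

    Returns a dict with the reference genome, virions, draft contig, reads
    and ground truth — the unit the pipeline (and the acceptance checks)
    iterate over.
    """
    params = params or simulate.PackagingParams()
    terminase_class = None if strategy is PackagingStrategy.ITR else strategy
    spec = simulate.SimGenomeSpec(
        length=length, gc=gc, terminase_class=terminase_class, seed=seed
    )
    genome = simulate.make_genome(spec)
    if host is None and strategy is PackagingStrategy.MU_LIKE:
        host = GenomeRecord(
            "sim_host",
            "".join(np.random.default_rng(seed + 17).choice(list("ACGT"), size=60_000)),
        )
    virions = simulate.package_virions(
        genome, strategy, n=n_virions, seed=seed + 1, params=params, host=host
    )
    if strategy in (PackagingStrategy.COS_5, PackagingStrategy.COS_3):
        virions = simulate.end_chemistry(
            virions, strategy, c=params.cos_overhang, seed=seed + 2
        )
    contig, truth = simulate.make_draft_contig(
        genome, strategy, virions, seed=seed + 3, params=params
    )
    n_pairs = simulate.n_pairs_for_depth(virions, depth)
    reads = simulate.shear_reads(
        virions, n_pairs, error_rate=error_rate, seed=seed + 4
    )
    return {
        "genome": genome,
        "virions": virions,
        "contig": contig,
        "reads": reads,
        "truth": truth,
        "strategy": strategy,
        "params": params,
    }


def _load_inputs(cfg) -> list[dict]:
    if "contigs" not in cfg or not ("reads" in cfg or "coverage" in cfg):
        raise ParameterError("real mode requires 'contigs' plus 'reads' or 'coverage'")
    contigs = seqio.read_fasta(cfg["contigs"])
    genomes = []
    for contig in contigs:
        entry = {"id": contig.id, "contig": contig, "reads": [], "truth": None,
                 "strategy": None, "genome": None, "virions": []}
        if "reads" in cfg:
            entry["reads"] = seqio.read_fastq(cfg["reads"])
        genomes.append(entry)
    return genomes


def _manifest(cfg, genomes, plans, standardized) -> dict:
    out = {
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "decisions": {},
        "hashes": {},
    }
    for g in genomes:
        gid = g["id"]
        out["decisions"][gid] = {
            "pattern": g["pattern"].label.value,
            "anchor": g["pattern"].anchor,
            "terminase": g["terminase"].reference_name if g["terminase"] else None,
            "strategy": plans[gid].strategy,
            "rationale": {k: v for k, v in plans[gid].rationale.items() if k != "group"},
        }
        out["hashes"][gid] = hashlib.sha256(
            standardized[gid].contig.sequence.encode()
        ).hexdigest()
    return out


def _write_outputs(out_dir: Path, artifacts) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(
        [s.contig for s in artifacts["standardized"].values()],
        out_dir / "standardized.fasta",
    )
    with open(out_dir / "plans.tsv", "w") as fh:
        fh.write("genome\tstrategy\tcut_pos\torientation\ttrim_left\ttrim_right\treference\n")
        for gid, plan in sorted(artifacts["plans"].items()):
            fh.write(
                f"{gid}\t{plan.strategy}\t{plan.cut_pos}\t{plan.orientation}\t"
                f"{plan.trim_left}\t{plan.trim_right}\t{plan.reference_id}\n"
            )
    with open(out_dir / "patterns.tsv", "w") as fh:
        fh.write("genome\tlabel\tanchor\tmedian_depth\n")
        for g in artifacts["genomes"]:
            p = g["pattern"]
            fh.write(f"{g['id']}\t{p.label.value}\t{p.anchor}\t{p.features.get('median_depth')}\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(artifacts["manifest"], fh, indent=2, default=str)
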