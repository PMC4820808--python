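"""End-to-end orchestration: simulate -> mask -> discover -> tandem-filter ->
map/classify -> burden statistics, with ChIP enrichment and phylogenetics as
parallel branches. Deterministic given (config, seed); every stage writes its
outputs to a stage-named subdirectory and the run ends with a
machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import synthetic
from .burden import compare_burdens
from .chip import from_multimapped_reads, permutation_poisson_test
from .discovery import DiscoveryParams, discover_repeats, mask_te
from .formats_io import write_bed, write_fasta, GenomicInterval
from .locality import (ConsensusMapper, LocalityParams, MappingParams,
                       classify_locality, compute_burden)
from .tandem import SplitParams, TandemParams, detect_tandem_arrays, split_tandem

log = logging.getLogger(__name__)

_DEFAULTS: dict = {
    "preset": "firre_like",
    "seed": 0,
    "outdir": "locrep_run",
    "discovery": dict(k=16, min_count=3, min_identity=0.8, x_drop=20.0,
                      length_penalty=2.0, min_length=50, max_extend=2000),
    "tandem": dict(min_period=1, max_period=2000, purity_min=0.8),
    "split": dict(tandem_overlap=0.5, gap_max=10, adjacent_frac=0.5),
    "mapping": dict(k_map=12, min_identity=0.7, min_length_fraction=0.5),
    "locality": dict(locality_min=0.8, inside_fraction=0.5, flank=0),
    "chip": dict(enabled=True, n_perm=100, cap=20),
    "phylo": dict(enabled=False, n_boot=100, model="jukes_cantor"),
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        base = json.loads(json.dumps(_DEFAULTS))
        _deep_update(base, overrides, path="")
        return cls(base)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def __getitem__(self, key):
        return self.values[key]

    def digest(self) -> str:
        # outdir is run metadata, not part of the scientific configuration
        stable = {k: v for k, v in self.values.items() if k != "outdir"}
        return hashlib.sha256(json.dumps(stable, sort_keys=True).encode()).hexdigest()[:12]


def _deep_update(base: dict, overrides: dict, path: str) -> None:
    for key, val in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here} must be a mapping")
            _deep_update(base[key], val, here)
        else:
            base[key] = val


def validate_config(config: RunConfig) -> list[tuple[str, str]]:
    """Range and consistency checks; returns (severity, message) findings."""
    v = config.values
    findings = []
    if v["preset"] not in synthetic.PRESETS:
        findings.append(("error", f"unknown preset {v['preset']!r}"))
    d = v["discovery"]
    if d["k"] < 8:
        findings.append(("error", "discovery.k must be >= 8"))
    for key in ("min_identity",):
        if not (0 <= d[key] <= 1):
            findings.append(("error", f"discovery.{key} must be in [0, 1]"))
    if not (0 <= v["tandem"]["purity_min"] <= 1):
        findings.append(("error", "tandem.purity_min must be in [0, 1]"))
    if not (0 <= v["locality"]["locality_min"] <= 1):
        findings.append(("error", "locality.locality_min must be in [0, 1]"))
    if not (0 <= v["split"]["tandem_overlap"] <= 1):
        findings.append(("error", "split.tandem_overlap must be in [0, 1]"))
    if v["chip"]["n_perm"] < 10:
        findings.append(("error", "chip.n_perm < 10 makes the Poisson rate unstable"))
    if v["chip"]["cap"] < 1:
        findings.append(("error", "chip.cap must be >= 1"))
    if v["discovery"]["min_count"] < 2:
        findings.append(("error", "discovery.min_count must be >= 2"))
    return findings


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a synthetic preset; returns the run summary dict."""
    findings = validate_config(config)
    errors = [msg for sev, msg in findings if sev == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    echoed = {k: v for k, v in config.values.items() if k != "outdir"}
    (outdir / "config.yaml").write_text(yaml.safe_dump(echoed, sort_keys=True))
    summary: dict = {"version": __version__, "config_hash": config.digest(),
                     "stages": {}, "timings_s": {}}
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    try:
        _run_stages(config, outdir, summary)
    except Exception as exc:  # pragma: no cover - error path
        summary["failed_stage"] = summary.get("current_stage", "?")
        _write_summary(outdir, summary)
        raise RuntimeError(f"stage {summary['failed_stage']} failed: {exc}") from exc
    marker.unlink()
    _write_summary(outdir, summary)
    return summary


def _write_summary(outdir: Path, summary: dict) -> None:
    # wall times are volatile; they go to the run log so summary.json stays
    # byte-identical across reruns of the same config
    volatile = {k: summary.get(k) for k in ("timings_s", "current_stage")}
    stable = {k: v for k, v in summary.items() if k not in volatile}
    (outdir / "summary.json").write_text(json.dumps(stable, indent=2, sort_keys=True) + "\n")
    (outdir / "run_log.json").write_text(json.dumps(volatile, indent=2, sort_keys=True) + "\n")


def _stage(summary: dict, name: str):
    summary["current_stage"] = name
    return time.perf_counter()


def _done(summary: dict, name: str, t0: float) -> None:
    summary["timings_s"][name] = round(time.perf_counter() - t0, 3)


def _run_stages(config: RunConfig, outdir: Path, summary: dict) -> None:
    seed = int(config["seed"])

    # --- simulate
    t0 = _stage(summary, "simulate")
    sim_dir = outdir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    cfg = synthetic.PRESETS[config["preset"]](seed)
    assembly, genes, te_intervals, truth = synthetic.simulate_genome(cfg)
    write_fasta(sim_dir / "genome.fa", assembly)
    write_bed(sim_dir / "te.bed", te_intervals)
    gene_ivs = [GenomicInterval(g.interval.chrom, g.interval.start, g.interval.end,
                                g.interval.strand, g.gene_id) for g in genes]
    write_bed(sim_dir / "genes.bed", gene_ivs)
    with open(sim_dir / "genes_meta.tsv", "w") as fh:
        fh.write("gene_id\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.biotype}\n")
    synthetic.write_truth(sim_dir, truth)
    summary["stages"]["simulate"] = dict(
        genome_bp=sum(assembly.lengths.values()), n_genes=len(genes),
        n_planted_families=len(cfg.planted_families),
        n_planted_local=sum(1 for s in cfg.planted_families if s.host_locus),
        n_tandem_arrays=len(cfg.tandem_specs), n_te=len(te_intervals))
    _done(summary, "simulate", t0)

    # --- mask + discover
    t0 = _stage(summary, "discover")
    disc_dir = outdir / "discover"
    disc_dir.mkdir(exist_ok=True)
    masked = mask_te(assembly, te_intervals)
    dparams = DiscoveryParams(**config["discovery"])
    families = discover_repeats(masked, dparams)
    write_fasta(disc_dir / "consensi.fa", {f.family_id: f.consensus for f in families})
    _write_instances_bed(disc_dir / "instances.bed", families)
    summary["stages"]["discover"] = dict(n_families=len(families))
    _done(summary, "discover", t0)

    # --- tandem detection + routing
    t0 = _stage(summary, "tandem")
    tan_dir = outdir / "tandem"
    tan_dir.mkdir(exist_ok=True)
    tparams = TandemParams(**config["tandem"])
    arrays = []
    for chrom, seq in masked.assembly.sequences.items():
        arrays.extend(detect_tandem_arrays(seq, tparams, chrom=chrom))
    tr_catalog, lr_candidates = split_tandem(families, arrays, SplitParams(**config["split"]))
    with open(tan_dir / "arrays.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tperiod\tcopy_number\tpurity\tmotif\n")
        for a in arrays:
            fh.write(f"{a.interval.chrom}\t{a.interval.start}\t{a.interval.end}\t"
                     f"{a.period}\t{a.copy_number:.2f}\t{a.purity:.4f}\t{a.motif}\n")
    write_bed(tan_dir / "arrays.bed", [a.interval for a in arrays])
    write_fasta(tan_dir / "lr_candidates.fa",
                {f.family_id: f.consensus for f in lr_candidates} or {"empty": "N"})
    summary["stages"]["tandem"] = dict(n_arrays=len(arrays), n_tr=len(tr_catalog),
                                       n_lr_candidates=len(lr_candidates))
    _done(summary, "tandem", t0)

    # --- genome-wide mapping + locality + burden
    t0 = _stage(summary, "classify")
    cls_dir = outdir / "classify"
    cls_dir.mkdir(exist_ok=True)
    mapper = ConsensusMapper(assembly, MappingParams(**config["mapping"]))
    lparams = LocalityParams(**config["locality"])
    calls, instance_map = [], {}
    for fam in lr_candidates:
        hits = mapper.map(fam.consensus)
        if len(hits) < 2:
            continue
        instance_map[fam.family_id] = hits
        calls.append(classify_locality(fam.family_id, hits, genes, lparams))
    with open(cls_dir / "locality.tsv", "w") as fh:
        fh.write("family_id\tcall\thost_locus\tlocality_fraction\tn_instances\n")
        for c in calls:
            fh.write(f"{c.family_id}\t{c.call}\t{c.host_locus or '.'}\t"
                     f"{c.locality_fraction:.3f}\t{c.n_instances}\n")
    burden_df = compute_burden(calls, instance_map, arrays, genes, assembly)
    burden_df.to_csv(cls_dir / "burden.tsv", sep="\t", index=False, float_format="%.6g")
    n_local = sum(1 for c in calls if c.call == "LOCAL")
    summary["stages"]["classify"] = dict(n_classified=len(calls), n_local=n_local,
                                         n_dispersed=len(calls) - n_local)
    _done(summary, "classify", t0)

    # --- burden comparison between biotype classes
    t0 = _stage(summary, "burden")
    bur_dir = outdir / "burden"
    bur_dir.mkdir(exist_ok=True)
    lnc = burden_df[burden_df.biotype == "lncRNA"]
    pc = burden_df[burden_df.biotype == "mRNA"]
    if len(lnc) and len(pc):
        cmp_lr = compare_burdens(lnc.lr_per_kb, pc.lr_per_kb, "lncRNA", "mRNA")
        cmp_tr = compare_burdens(lnc.tr_per_kb, pc.tr_per_kb, "lncRNA", "mRNA")
        cmp_lr.cdf_table.to_csv(bur_dir / "lr_cdf.tsv", sep="\t", index=False)
        summary["stages"]["burden"] = dict(
            lr_p=cmp_lr.p_value, tr_p=cmp_tr.p_value,
            lnc_mean_lr_per_kb=float(lnc.lr_per_kb.mean()),
            mrna_mean_lr_per_kb=float(pc.lr_per_kb.mean()))
    _done(summary, "burden", t0)

    # --- ChIP branch
    if config["chip"]["enabled"]:
        t0 = _stage(summary, "chip")
        chip_dir = outdir / "chip"
        chip_dir.mkdir(exist_ok=True)
        bound = cfg.chip_model.bound_family
        bound_ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                     for r in truth.family_instances(bound).itertuples()]
        chip_reads, input_reads = synthetic.simulate_chip_reads(
            assembly, bound_ivs, cfg.chip_model, seed + 1)
        synthetic.write_sam(chip_dir / "chip.sam", assembly, chip_reads)
        synthetic.write_sam(chip_dir / "input.sam", assembly, input_reads)
        cap = config["chip"]["cap"]
        chip_set = from_multimapped_reads(chip_reads, assembly.lengths, cap)
        input_set = from_multimapped_reads(input_reads, assembly.lengths, cap)
        res = permutation_poisson_test(bound, bound_ivs, assembly, chip_set, input_set,
                                       n_perm=config["chip"]["n_perm"], seed=seed + 2)
        summary["stages"]["chip"] = dict(family=bound, enrichment=res.enrichment,
                                         lam=res.lam, p_value=res.p_value)
        _done(summary, "chip", t0)


def _write_instances_bed(path: Path, families) -> None:
    ivs, scores = [], []
    for fam in families:
        for iv, ident in fam.instances:
            ivs.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, fam.family_id))
            scores.append(ident * 1000)
    write_bed(path, ivs, scores)
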