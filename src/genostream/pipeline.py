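"""End-to-end orchestration from a single declarative config.

A run executes the requested stages in dependency order — per-genome
streamlining profiles, pangenome construction, ANI/AAI matrices, read
recruitment with RPKG, module scanning and the indicator-panel
statistics — and writes a reproducibility manifest (package version,
seeds, thresholds, input/output checksums).  All threshold defaults are
the study cutoffs, so a bare run speaks the published protocol.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

import genostream
from genostream import io as gio
from genostream import metrics, pangenome, recruit as grecruit, stats
from genostream.identity import classify_rank, compute_aai, compute_ani
from genostream.profiles import build_module_profiles, load_module_definitions, module_matrix, scan

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "ortholog_identity": 50.0, "ortholog_coverage": 50.0,
    "paralog_identity": 50.0, "paralog_similarity": 70.0,
    "paralog_coverage": 80.0,
    "recruit_min_length": 50, "recruit_min_identity": 95.0,
    "recruit_max_evalue": 1e-5,
    "module_cluster_identity": 90.0, "module_cluster_coverage": 90.0,
    "module_scan_max_evalue": 1e-3,
    "aai_min_identity": 30.0, "aai_min_coverage": 70.0,
    "ani_fragment_bp": 1020, "ani_min_identity": 30.0,
    "ani_min_alignable": 70.0,
    "species_ani": 95.0, "genus_aai_low": 65.0, "genus_aai_high": 70.0,
    "alpha": 0.05,
}

_PERCENT_KEYS = [k for k in DEFAULT_THRESHOLDS
                 if k.endswith(("identity", "coverage", "similarity",
                                "alignable"))]

ALL_STAGES = ["profiles", "pangenome", "ani", "aai", "recruit", "modules",
              "figstats"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; dependents were skipped."""


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    genomes: list[dict] = dc_field(default_factory=list)
    metagenomes: list[dict] = dc_field(default_factory=list)
    modules: dict | None = None
    stages: list[str] = dc_field(default_factory=lambda: list(ALL_STAGES))
    thresholds: dict = dc_field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(raw.get("thresholds") or {})
        for key in _PERCENT_KEYS:
            if not 0 <= float(thr[key]) <= 100:
                raise ConfigError(
                    f"threshold {key}={thr[key]} outside [0, 100]")
        if thr["recruit_max_evalue"] < 0 or thr["module_scan_max_evalue"] < 0:
            raise ConfigError("e-value thresholds must be non-negative")
        stages = raw.get("stages") or list(ALL_STAGES)
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        genomes = []
        for g in raw.get("genomes") or []:
            entry = {"id": g["id"], "fasta": resolve(g["fasta"]),
                     "gff3": resolve(g["gff3"]) if g.get("gff3") else None}
            for key in ("fasta", "gff3"):
                if entry[key] is not None and not Path(entry[key]).exists():
                    raise ConfigError(f"genome {g['id']}: missing {key} "
                                      f"{entry[key]}")
            genomes.append(entry)
        metagenomes = []
        for m in raw.get("metagenomes") or []:
            entry = {"id": m["id"], "path": resolve(m["path"]),
                     "ecosystem": m.get("ecosystem", "other")}
            if not Path(entry["path"]).exists():
                raise ConfigError(f"metagenome {m['id']}: missing path "
                                  f"{entry['path']}")
            metagenomes.append(entry)
        modules = None
        if raw.get("modules"):
            modules = {"table": resolve(raw["modules"]["table"]),
                       "fasta": resolve(raw["modules"]["fasta"])}
            for k, p in modules.items():
                if not Path(p).exists():
                    raise ConfigError(f"modules: missing {k} {p}")
        return cls(output_dir=resolve(raw.get("output_dir", "genostream_out")),
                   genomes=genomes, metagenomes=metagenomes, modules=modules,
                   stages=stages, thresholds=thr,
                   seed=int(raw.get("seed", 0)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure is recorded and halts stages that depend on it;
    independent stages still run and partial outputs are kept.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "package_version": genostream.__version__,
        "seed": config.seed,
        "thresholds": {k: thr[k] for k in sorted(thr)},
        "inputs": {}, "outputs": {}, "stages": {},
    }
    for g in config.genomes:
        manifest["inputs"][g["id"]] = {
            k: _sha256(Path(v)) for k, v in (("fasta", g["fasta"]),
                                             ("gff3", g["gff3"])) if v}
    for m in config.metagenomes:
        manifest["inputs"][m["id"]] = {"reads": _sha256(Path(m["path"]))}

    genomes: dict[str, gio.GenomeRecord] = {}
    proteomes: dict[str, gio.ProteinSet] = {}
    for g in config.genomes:
        rec = gio.load_genome(g["fasta"], g["gff3"], genome_id=g["id"])
        genomes[g["id"]] = rec
        proteomes[g["id"]] = gio.extract_proteins(rec)

    failed: set[str] = set()

    def record(stage, path=None, error=None):
        if error is not None:
            failed.add(stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(error)}
            log.error("stage %s failed: %s", stage, error)
        else:
            manifest["stages"][stage] = {"status": "ok"}
            if path is not None:
                manifest["outputs"][Path(path).name] = _sha256(Path(path))

    paralog_counts: dict[str, int] = {}
    if "pangenome" in config.stages and len(genomes) >= 2:
        try:
            fams = pangenome.build_families(
                list(proteomes.values()),
                min_identity=thr["ortholog_identity"],
                min_coverage=thr["ortholog_coverage"])
            summ = pangenome.core_pan_summary(fams, seed=config.seed)
            fam_path = out / "families.tsv"
            fams.to_table().to_csv(fam_path, sep="\t", index=False)
            record("pangenome", fam_path)
            mat_path = out / "presence_matrix.tsv"
            fams.presence_matrix(counts=True).to_csv(mat_path, sep="\t")
            manifest["outputs"][mat_path.name] = _sha256(mat_path)
            manifest["stages"]["pangenome"].update(
                pan_families=summ.pan_families, core_families=summ.core_families,
                core_fraction_percent=summ.core_fraction_percent)
            pangenome.export_single_copy_core(
                fams, list(proteomes.values()), out / "single_copy_core")
        except Exception as e:  # noqa: BLE001 - stage isolation
            record("pangenome", error=e)

    if "profiles" in config.stages and genomes:
        try:
            profs = []
            for gid, rec in genomes.items():
                n_par, _ = pangenome.find_paralogs(
                    proteomes[gid],
                    min_identity=thr["paralog_identity"],
                    min_similarity=thr["paralog_similarity"],
                    min_coverage=thr["paralog_coverage"])
                paralog_counts[gid] = n_par
                profs.append(metrics.streamlining_profile(
                    rec, proteomes[gid], n_par))
            p_path = out / "profiles.tsv"
            metrics.profiles_to_tsv(p_path, profs)
            record("profiles", p_path)
        except Exception as e:  # noqa: BLE001
            record("profiles", error=e)

    if "ani" in config.stages and len(genomes) >= 2:
        try:
            ids = sorted(genomes)
            mat = pd.DataFrame(100.0, index=ids, columns=ids)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    r = compute_ani(genomes[a], genomes[b],
                                    fragment_bp=int(thr["ani_fragment_bp"]),
                                    min_identity=thr["ani_min_identity"],
                                    min_alignable=thr["ani_min_alignable"])
                    mat.loc[a, b] = mat.loc[b, a] = (
                        r.ani_percent if r.defined else float("nan"))
            path = out / "ani_matrix.tsv"
            mat.to_csv(path, sep="\t")
            record("ani", path)
        except Exception as e:  # noqa: BLE001
            record("ani", error=e)

    if "aai" in config.stages and len(genomes) >= 2:
        try:
            ids = sorted(genomes)
            mat = pd.DataFrame(100.0, index=ids, columns=ids)
            ranks = []
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    r = compute_aai(proteomes[a], proteomes[b],
                                    min_identity=thr["aai_min_identity"],
                                    min_coverage=thr["aai_min_coverage"])
                    mat.loc[a, b] = mat.loc[b, a] = (
                        r.aai_percent if r.defined else float("nan"))
                    if r.defined:
                        ranks.append((a, b, r.aai_percent, classify_rank(
                            r, species_cut=thr["species_ani"],
                            genus_cut_low=thr["genus_aai_low"],
                            genus_cut_high=thr["genus_aai_high"])))
            path = out / "aai_matrix.tsv"
            mat.to_csv(path, sep="\t")
            record("aai", path)
            rk_path = out / "rank_calls.tsv"
            pd.DataFrame(ranks, columns=["genome_a", "genome_b", "aai",
                                         "rank_call"]).to_csv(
                rk_path, sep="\t", index=False)
            manifest["outputs"][rk_path.name] = _sha256(rk_path)
        except Exception as e:  # noqa: BLE001
            record("aai", error=e)

    if "recruit" in config.stages and genomes and config.metagenomes:
        try:
            read_sets = [grecruit.read_set_from_fastx(
                m["path"], m["id"], m["ecosystem"]) for m in config.metagenomes]
            results = []
            for rec in genomes.values():
                masked = gio.mask_rrna(rec)
                for rs in read_sets:
                    results.append(grecruit.recruit(
                        rs, masked,
                        min_length=int(thr["recruit_min_length"]),
                        min_identity=thr["recruit_min_identity"],
                        max_evalue=thr["recruit_max_evalue"]))
            table = grecruit.rpkg_table(results, genomes.values(), read_sets)
            path = out / "rpkg.tsv"
            table.to_csv(path, sep="\t", index=False)
            record("recruit", path)
            eco_path = out / "rpkg_ecosystem_max.tsv"
            grecruit.summarize_by_ecosystem(table).to_csv(
                eco_path, sep="\t", index=False)
            manifest["outputs"][eco_path.name] = _sha256(eco_path)
        except Exception as e:  # noqa: BLE001
            record("recruit", error=e)

    if "modules" in config.stages and config.modules and genomes:
        try:
            mods = load_module_definitions(config.modules["table"],
                                           config.modules["fasta"])
            models = build_module_profiles(
                mods, identity=thr["module_cluster_identity"],
                coverage=thr["module_cluster_coverage"], seed=config.seed)
            hits_by_genome = {
                gid: scan(proteomes[gid], models,
                          max_evalue=thr["module_scan_max_evalue"])
                for gid in genomes}
            mat = module_matrix(hits_by_genome, mods, models)
            path = out / "module_matrix.tsv"
            mat.to_csv(path, sep="\t")
            record("modules", path)
        except Exception as e:  # noqa: BLE001
            record("modules", error=e)

    if "figstats" in config.stages and "profiles" not in failed and genomes:
        try:
            profs = metrics.profiles_from_tsv(out / "profiles.tsv")
            if len(profs) >= 3:
                report = stats.streamlining_report(profs, alpha=thr["alpha"])
                path = out / "panel_stats.tsv"
                report.to_csv(path, sep="\t", index=False)
                record("figstats", path)
            else:
                manifest["stages"]["figstats"] = {
                    "status": "skipped", "reason": "needs >=3 genomes"}
        except Exception as e:  # noqa: BLE001
            record("figstats", error=e)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
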