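"""End-to-end orchestration: simulate -> parse -> project -> transform ->
cluster -> sPLS-DA / PERMANOVA -> differential markers.

Each stage reads and writes plain-text TSV/JSON under a run directory and
is individually resumable: a stage whose declared outputs already exist is
skipped on re-run.  A run manifest records the configuration digest, input
digests, per-stage status and every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation_io, differential, multivariate, projection, synthetic_data, transforms

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for every pipeline stage; one master seed, per-stage
    seeds derived deterministically from stage names."""

    outdir: str = "cazytype_run"
    seed: int = 0
    simulate: bool = True
    divisor_mode: str = "panel_mean"
    min_tools: int = 2
    include_hmmer: bool = False
    linkage: str = "average"
    zscore_ddof: int = 1
    cluster_cut_k: int = 2
    splsda_components: int = 2
    splsda_grid: tuple = (1, 2, 5, 10, 20)
    splsda_folds: int = 5
    splsda_repeats: int = 10
    splsda_distance: str = "max_dist"
    permanova_permutations: int = 999
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    contrasts: tuple = differential.DEFAULT_CONTRASTS
    resume: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        return cfg

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def simulation_config(self) -> synthetic_data.SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.stage_seed("simulate"))
        return synthetic_data.SimulationConfig(**params)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config_digest: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, outputs: list[Path]) -> None:
        self.stages[stage] = status
        for p in outputs:
            self.outputs[str(p)] = _sha256(p) if p.exists() else "missing"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1))


class StageFailure(RuntimeError):
    """A pipeline stage failed; downstream outputs were not produced."""


# --------------------------------------------------------------------------
# stage implementations (paths relative to the run directory)
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    sim = cfg.simulation_config()
    panel = synthetic_data.simulate_reference_panel(sim)
    cohort = synthetic_data.simulate_cohort(sim, panel)
    fixtures = outdir / "fixtures"
    synthetic_data.write_fixtures(panel, fixtures, truth=cohort.truth)
    cohort.profile.to_tsv(outdir / "profile.tsv", outdir / "reads.tsv")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    cohort.truth.to_json(outdir / "ground_truth.json")
    panel.table.to_tsv(outdir / "panel_table.tsv")
    return [
        fixtures / "manifest.tsv",
        outdir / "profile.tsv",
        outdir / "reads.tsv",
        outdir / "metadata.tsv",
        outdir / "ground_truth.json",
    ]


def stage_parse(cfg: RunConfig, outdir: Path) -> list[Path]:
    tools = annotation_io.OVERVIEW_TOOLS if cfg.include_hmmer else annotation_io.DEFAULT_TOOLS
    table = annotation_io.load_annotation_directory(
        outdir / "fixtures" / "manifest.tsv", min_tools=cfg.min_tools, tools=tools
    )
    table.to_tsv(outdir / "genome_table.tsv")
    shares = annotation_io.class_shares(table)
    shares.rename("share_pct").to_csv(outdir / "class_shares.tsv", sep="\t")
    contrib = annotation_io.phylum_family_contribution(table)
    contrib.to_csv(outdir / "phylum_contribution.tsv", sep="\t", index_label="family")
    return [outdir / "genome_table.tsv", outdir / "class_shares.tsv",
            outdir / "phylum_contribution.tsv"]


def stage_project(cfg: RunConfig, outdir: Path) -> list[Path]:
    table = annotation_io.GenomeCazymeTable.from_tsv(outdir / "genome_table.tsv")
    profile = projection.TaxonomicProfile.from_tsv(
        outdir / "profile.tsv", outdir / "reads.tsv"
    )
    matrix = projection.build_abundance_matrix(table, profile, cfg.divisor_mode)
    matrix.to_tsv(outdir / "abundance.tsv")
    (outdir / "abundance.json").write_text(json.dumps(matrix.provenance, indent=1))
    return [outdir / "abundance.tsv", outdir / "abundance.json"]


def stage_transform(cfg: RunConfig, outdir: Path) -> list[Path]:
    ab = pd.read_csv(outdir / "abundance.tsv", sep="\t", index_col="sample_id")
    logged = transforms.log_transform(ab)
    std = transforms.z_standardize(logged, ddof=cfg.zscore_ddof)
    std.values.to_csv(outdir / "standardized.tsv", sep="\t", index_label="sample_id")
    (outdir / "standardized.json").write_text(
        json.dumps({"ddof": std.ddof, "degenerate_families": list(std.degenerate)})
    )
    return [outdir / "standardized.tsv", outdir / "standardized.json"]


def stage_cluster(cfg: RunConfig, outdir: Path) -> list[Path]:
    std = pd.read_csv(outdir / "standardized.tsv", sep="\t", index_col="sample_id")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    keep = [c for c in std.columns if std[c].nunique() > 1]
    outputs = []
    for axis, name in ((0, "samples"), (1, "families")):
        dist = transforms.spearman_distance(std[keep], axis=axis)
        dendro = transforms.hierarchical_cluster(dist, method=cfg.linkage)
        path = outdir / f"dendrogram_{name}.nwk"
        dendro.write_newick(path)
        cut = dendro.cut(cfg.cluster_cut_k)
        cut_path = outdir / f"clusters_{name}_k{cfg.cluster_cut_k}.tsv"
        cut.to_csv(cut_path, sep="\t", index_label=name[:-1] + "_id")
        outputs += [path, cut_path]
        if name == "samples":
            agreement = pd.crosstab(cut, meta["body_site"])
            agreement.to_csv(outdir / "cluster_site_crosstab.tsv", sep="\t")
            outputs.append(outdir / "cluster_site_crosstab.tsv")
    return outputs


def _load_standardized(outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    std = pd.read_csv(outdir / "standardized.tsv", sep="\t", index_col="sample_id")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    degenerate = json.loads((outdir / "standardized.json").read_text())[
        "degenerate_families"
    ]
    x = std.drop(columns=[c for c in degenerate if c in std.columns])
    return x, meta.loc[std.index]


def stage_splsda(cfg: RunConfig, outdir: Path) -> list[Path]:
    x, meta = _load_standardized(outdir)
    y = meta["body_site"]
    grid = [g for g in cfg.splsda_grid if g <= x.shape[1]]
    tuning = multivariate.tune_keepx(
        x, y, grid,
        n_components=cfg.splsda_components,
        folds=cfg.splsda_folds,
        repeats=cfg.splsda_repeats,
        distance=cfg.splsda_distance,
        seed=cfg.stage_seed("splsda"),
    )
    tuning.to_tsv(outdir / "splsda_tuning.tsv")
    model = multivariate.fit_splsda(
        x, y, keepx=tuning.chosen_keepx, n_components=cfg.splsda_components
    )
    scores = pd.DataFrame(
        model.scores,
        index=x.index,
        columns=[f"comp{h+1}" for h in range(model.n_components)],
    )
    scores.to_csv(outdir / "splsda_scores.tsv", sep="\t", index_label="sample_id")
    model.loadings_frame().to_csv(
        outdir / "splsda_loadings.tsv", sep="\t", index_label="family"
    )
    summary = {
        "chosen_keepX": tuning.chosen_keepx,
        "cv_error": [float(tuning.mean_error.loc[k, f"comp{h+1}"])
                     for h, k in enumerate(tuning.chosen_keepx)],
        "null_error": multivariate.null_model_error(y),
    }
    (outdir / "splsda_summary.json").write_text(json.dumps(summary, indent=1))
    return [outdir / "splsda_tuning.tsv", outdir / "splsda_scores.tsv",
            outdir / "splsda_loadings.tsv", outdir / "splsda_summary.json"]


def stage_permanova(cfg: RunConfig, outdir: Path) -> list[Path]:
    x, meta = _load_standardized(outdir)
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(x.to_numpy(float)))
    results = {}
    for factor in ("body_site", "phenotype"):
        res = multivariate.permanova(
            dist,
            meta[factor],
            n_permutations=cfg.permanova_permutations,
            seed=cfg.stage_seed(f"permanova:{factor}"),
        )
        results[factor] = res.to_dict()
    path = outdir / "permanova.json"
    path.write_text(json.dumps(results, indent=1))
    return [path]


def stage_diff(cfg: RunConfig, outdir: Path) -> list[Path]:
    ab = pd.read_csv(outdir / "abundance.tsv", sep="\t", index_col="sample_id")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    cm = differential.round_abundances(ab, meta[["phenotype", "body_site"]])
    results = differential.run_contrasts(cm, contrasts=cfg.contrasts)
    outputs = []
    for label, res in results.items():
        differential.call_markers(
            res, lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold
        )
        path = outdir / f"diff_{label}.tsv"
        res.to_tsv(path)
        volcano = differential.call_markers(
            res, lfc_threshold=cfg.lfc_threshold, fdr_threshold=cfg.fdr_threshold
        )
        vpath = outdir / f"volcano_{label}.tsv"
        volcano.to_csv(vpath, sep="\t", index_label="family")
        outputs += [path, vpath]
    return outputs


def stage_report(cfg: RunConfig, outdir: Path) -> list[Path]:
    report: dict = {"markers": {}}
    for path in sorted(outdir.glob("diff_*.tsv")):
        label = path.stem[len("diff_"):]
        table = pd.read_csv(path, sep="\t", index_col="family")
        report["markers"][label] = {
            "n_markers": int(table["marker"].sum()),
            "enriched": sorted(table.index[table["direction"] == "enriched"]),
            "depleted": sorted(table.index[table["direction"] == "depleted"]),
        }
    truth_path = outdir / "ground_truth.json"
    if truth_path.exists():
        truth = synthetic_data.GroundTruth.from_json(truth_path)
        scores = {}
        contrasts = {f"{e['phenotype']}_vs_control" for e in truth.effects}
        for label in contrasts:
            table_path = outdir / f"diff_{label}.tsv"
            if table_path.exists():
                table = pd.read_csv(table_path, sep="\t", index_col="family")
                called = list(table.index[table["marker"]])
                scores[label] = synthetic_data.score_calls(called, truth, label)
        report["scoring"] = scores
    perm_path = outdir / "permanova.json"
    if perm_path.exists():
        report["permanova"] = json.loads(perm_path.read_text())
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=1))
    return [path]


STAGES = [
    ("simulate", stage_simulate),
    ("parse", stage_parse),
    ("project", stage_project),
    ("transform", stage_transform),
    ("cluster", stage_cluster),
    ("splsda", stage_splsda),
    ("permanova", stage_permanova),
    ("diff", stage_diff),
    ("report", stage_report),
]


def expected_outputs(name: str, cfg: RunConfig, outdir: Path) -> list[Path]:
    """The files a stage must leave behind, for resume checks."""
    if name == "simulate":
        return [outdir / "fixtures" / "manifest.tsv", outdir / "profile.tsv",
                outdir / "reads.tsv", outdir / "metadata.tsv",
                outdir / "ground_truth.json"]
    if name == "parse":
        return [outdir / "genome_table.tsv"]
    if name == "project":
        return [outdir / "abundance.tsv", outdir / "abundance.json"]
    if name == "transform":
        return [outdir / "standardized.tsv", outdir / "standardized.json"]
    if name == "cluster":
        return [outdir / "dendrogram_samples.nwk", outdir / "dendrogram_families.nwk"]
    if name == "splsda":
        return [outdir / "splsda_summary.json"]
    if name == "permanova":
        return [outdir / "permanova.json"]
    if name == "diff":
        return [outdir / f"diff_{lvl}_vs_{ref}.tsv" for _, lvl, ref in cfg.contrasts]
    if name == "report":
        return [outdir / "report.json"]
    return []


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute the pipeline stage by stage.

    A stage whose declared outputs all exist is skipped when
    ``cfg.resume`` is set (deleting an intermediate and re-running
    regenerates it and everything downstream of it); a stage failure
    halts the run with the failing stage named and leaves downstream
    outputs absent.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_digest = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_digest=config_digest)

    rerun_downstream = False
    for name, func in STAGES:
        if stages is not None and name not in stages:
            continue
        if name == "simulate" and not cfg.simulate:
            manifest.stages[name] = "skipped (external inputs)"
            continue
        declared = expected_outputs(name, cfg, outdir)
        if (
            cfg.resume
            and not rerun_downstream
            and declared
            and all(p.exists() for p in declared)
        ):
            manifest.record(name, "skipped (outputs present)", declared)
            continue
        rerun_downstream = True
        t0 = time.monotonic()
        try:
            outputs = func(cfg, outdir)
        except Exception as exc:
            manifest.record(name, f"failed: {exc}", [])
            manifest.write(outdir / "run_manifest.json")
            raise StageFailure(f"stage {name!r} failed: {exc}") from exc
        missing = [p for p in outputs if not p.exists()]
        if missing:
            raise StageFailure(f"stage {name!r} did not produce {missing}")
        manifest.record(name, f"ok ({time.monotonic() - t0:.1f}s)", outputs)
        manifest.write(outdir / "run_manifest.json")
    return manifest


def validate_inputs(outdir: str | Path) -> list[str]:
    """Schema and cross-reference checks on a run directory's inputs.

    Returns a list of human-readable violations (empty = valid).
    """
    outdir = Path(outdir)
    violations: list[str] = []
    profile_path = outdir / "profile.tsv"
    reads_path = outdir / "reads.tsv"
    meta_path = outdir / "metadata.tsv"
    manifest_path = outdir / "fixtures" / "manifest.tsv"

    profile = None
    if not profile_path.exists():
        violations.append(f"missing file: {profile_path}")
    else:
        ab = pd.read_csv(profile_path, sep="\t", index_col="sample_id")
        neg = np.argwhere(ab.to_numpy() < 0)
        for i, j in neg:
            violations.append(
                f"negative abundance at sample {ab.index[i]!r}, strain {ab.columns[j]!r}"
            )
        over = ab.sum(axis=1)
        for sid in over.index[over > 1 + 1e-6]:
            violations.append(f"sample {sid!r} abundances sum above 1")
        profile = ab
    if reads_path.exists():
        reads = pd.read_csv(reads_path, sep="\t", index_col="sample_id")["total_reads"]
        for sid in reads.index[reads <= 0]:
            violations.append(f"sample {sid!r} has non-positive total reads")
    else:
        violations.append(f"missing file: {reads_path}")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        try:
            projection.validate_metadata(meta)
        except ValueError as exc:
            violations.append(str(exc))
        if profile is not None:
            missing = set(profile.index) - set(meta.index)
            for sid in sorted(missing):
                violations.append(f"sample {sid!r} in profile missing from metadata")
    else:
        violations.append(f"missing file: {meta_path}")
    if manifest_path.exists() and profile is not None:
        manifest = annotation_io.read_manifest(manifest_path)
        unknown = set(profile.columns) - set(manifest.index)
        for strain in sorted(unknown):
            violations.append(f"strain {strain!r} in profile missing from panel")
    return violations
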