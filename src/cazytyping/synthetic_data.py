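"""Synthetic reference panels and metagenome cohorts.

The generator emulates the statistical structure the analysis assumes:
strains organised into genera and phyla with genus-blocked CAZyme
copy-number enrichment, genome sizes positively correlated with total
CAZyme copies, paired oral/gut samples per subject drawn from
site-specific strain pools with log-normal compositional abundances and
log-uniform read depths, and sparse planted disease effects that deplete
(or enrich) a few families in one phenotype.  Every quantity needed to
score downstream marker calls is recorded in a ground-truth ledger, and
the panel can be serialised as dbCAN2-style overview fixture files that
round-trip exactly through the annotation reader.

Planted families are made exclusive to one dedicated carrier strain each
(distinct carriers, forced into the gut pool).  Scaling that carrier's
abundance then moves the planted family by almost exactly the configured
fold change while families the carrier shares with its genus mates move
far less than the marker threshold, so the ledger's planted set is the
complete set of truly differential families.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    CAZY_CLASSES,
    GenomeCazymeTable,
)
from .projection import TaxonomicProfile, validate_metadata

DEFAULT_FAMILIES_PER_CLASS = {"GH": 40, "GT": 20, "CE": 8, "PL": 6, "CBM": 4, "AA": 2}
PAPER_SCALE_FAMILIES = {"GH": 116, "GT": 43, "PL": 19, "CE": 22, "CBM": 15, "AA": 5}

PHYLUM_NAMES = (
    "Firmicutes",
    "Bacteroidota",
    "Actinobacteria",
    "Proteobacteria",
    "Fusobacteria",
    "Verrucomicrobia",
    "Nitrospirae",
    "Spirochaetes",
    "Synergistetes",
)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential-abundance effect.

    ``family`` None lets the generator designate a dedicated marker family
    with a single carrier strain; a named family uses all its carriers.
    """

    family: str | None
    phenotype: str
    fold_change: float
    direction: str = "depleted"  # or "enriched"

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.direction not in ("depleted", "enriched"):
            raise ValueError(f"unknown direction: {self.direction!r}")


def _default_planted() -> list[PlantedEffect]:
    return [PlantedEffect(None, "T1D", 8.0, "depleted") for _ in range(5)]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the scaled-down preset (60 strains / 12 genera / 4 phyla /
    80 families, 30 subjects per phenotype) so the full pipeline runs in
    minutes; :meth:`paper_scale` switches to the full cohort dimensions.
    """

    n_strains: int = 60
    n_genera: int = 12
    n_phyla: int = 4
    families_per_class: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES_PER_CLASS)
    )
    core_fraction: float = 0.2
    enrichment_strength: float = 7.0
    accessory_home_genera: int = 2
    base_mean_core: float = 2.0
    base_mean_accessory: float = 0.6
    genome_size_base: float = 2.0e6
    genome_size_slope: float = 2.0e4
    target_r2: float = 0.72
    n_subjects_per_phenotype: int = 30
    phenotypes: tuple = ("control", "CRC", "T1D", "RA")
    site_overlap: float = 0.0
    mu_log: float = 0.0
    sigma_log: float = 0.5
    depth_range: tuple = (1.0e6, 1.0e7)
    planted_effects: list = field(default_factory=_default_planted)
    decoy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_strains, self.n_genera, self.n_phyla) < 1:
            raise ValueError("counts must be positive")
        if self.n_genera > self.n_strains or self.n_phyla > self.n_genera:
            raise ValueError("need n_strains >= n_genera >= n_phyla")
        if not 0.0 <= self.site_overlap <= 1.0:
            raise ValueError("site overlap fraction must lie in [0, 1]")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target r^2 must lie strictly inside (0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth range must be positive and ordered")

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationConfig":
        """Full-cohort preset: 310 strains / 86 genera / 9 phyla / 220
        families, 117 subjects per phenotype (slow)."""
        params = dict(
            n_strains=310,
            n_genera=86,
            n_phyla=9,
            families_per_class=dict(PAPER_SCALE_FAMILIES),
            n_subjects_per_phenotype=117,
        )
        params.update(overrides)
        return cls(**params)

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the single seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class ReferencePanel:
    """A simulated reference panel: the copy table, the gene-level truth
    behind it, and the planted-marker designations."""

    table: GenomeCazymeTable
    gene_lists: dict  # strain -> list of (gene_id, tuple of family ids)
    planted: list  # dicts: family, phenotype, fold_change, direction, carriers
    config: SimulationConfig


@dataclass
class GroundTruth:
    """Everything needed to score marker calls against the simulation."""

    effects: list  # family, phenotype, direction, fold_change, carriers, achieved_log2fc
    gene_lists: dict
    decoys: dict  # strain -> number of single-tool decoy genes written

    def planted_families(self, contrast: str | None = None) -> set:
        fams = set()
        for e in self.effects:
            if contrast is None or f"{e['phenotype']}_vs_control" == contrast:
                fams.add(e["family"])
        return fams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": self.effects,
            "decoys": self.decoys,
            "gene_lists": {
                s: [[g, list(f)] for g, f in genes]
                for s, genes in self.gene_lists.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gene_lists = {
            s: [(g, tuple(f)) for g, f in genes]
            for s, genes in payload["gene_lists"].items()
        }
        return cls(
            effects=payload["effects"], gene_lists=gene_lists, decoys=payload["decoys"]
        )


def _family_ids(families_per_class: dict) -> list[str]:
    ids = []
    for cls_ in CAZY_CLASSES:
        for i in range(families_per_class.get(cls_, 0)):
            ids.append(f"{cls_}{i + 1}")
    return ids


def simulate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Draw a genus-blocked reference panel of CAZyme gene repertoires.

    Family copy numbers are Poisson with genus-dependent means: core
    families share a common mean everywhere; accessory families have an
    elevated mean ``base * (1 + s)`` in their few home genera and a
    suppressed mean ``base / (1 + s)`` elsewhere, with ``s`` the
    enrichment strength (``s = 0`` removes all genus structure).  Genome
    sizes are linear in total copies with Gaussian noise scaled so the
    population squared correlation matches the configured target.
    """
    rng = config.rng(0)
    families = _family_ids(config.families_per_class)
    n_fam = len(families)
    strains = [f"strain{i + 1:03d}" for i in range(config.n_strains)]
    genera = [f"Genus{i + 1:02d}" for i in range(config.n_genera)]
    phyla = [PHYLUM_NAMES[i % len(PHYLUM_NAMES)] for i in range(config.n_phyla)]

    genus_of = np.arange(config.n_strains) % config.n_genera
    phylum_of_genus = np.arange(config.n_genera) % config.n_phyla

    n_core = max(int(round(config.core_fraction * n_fam)), 1)
    core_idx = rng.choice(n_fam, size=n_core, replace=False)
    is_core = np.zeros(n_fam, dtype=bool)
    is_core[core_idx] = True

    # genus-blocked Poisson means
    s = config.enrichment_strength
    means = np.zeros((config.n_strains, n_fam))
    home = {}
    for f in range(n_fam):
        if is_core[f]:
            means[:, f] = config.base_mean_core
        else:
            k = min(config.accessory_home_genera, config.n_genera)
            home_g = rng.choice(config.n_genera, size=k, replace=False)
            home[f] = set(int(g) for g in home_g)
            in_home = np.isin(genus_of, home_g)
            means[:, f] = np.where(
                in_home,
                config.base_mean_accessory * (1.0 + s),
                config.base_mean_accessory / (1.0 + s),
            )
    counts = rng.poisson(means)

    # designate planted marker families: exclusive to one carrier strain
    planted: list[dict] = []
    accessory = [i for i in range(n_fam) if not is_core[i]]
    auto_pool = [i for i in accessory if families[i].startswith("GH")]
    used_fams: set[int] = set()
    used_carriers: set[int] = set()
    used_genera: set[int] = set()
    for effect in config.planted_effects:
        if effect.family is None:
            candidates = [i for i in auto_pool if i not in used_fams]
            if not candidates:
                raise ValueError("not enough accessory GH families to auto-plant")
            fi = candidates[0]
            # carrier from an unused genus, to keep collateral depletion local
            carrier = None
            for sidx in range(config.n_strains):
                if sidx in used_carriers or int(genus_of[sidx]) in used_genera:
                    continue
                carrier = sidx
                break
            if carrier is None:
                raise ValueError("not enough strains to host planted families")
            counts[:, fi] = 0
            counts[carrier, fi] = rng.poisson(3.0) + 2
            carriers = [strains[carrier]]
            used_fams.add(fi)
            used_carriers.add(carrier)
            used_genera.add(int(genus_of[carrier]))
            fam_id = families[fi]
        else:
            fam_id = effect.family
            if fam_id not in families:
                raise ValueError(f"planted family {fam_id!r} not in the panel")
            fi = families.index(fam_id)
            carriers = [strains[j] for j in np.flatnonzero(counts[:, fi] > 0)]
            if not carriers:
                raise ValueError(f"planted family {fam_id!r} has no carrier strains")
        planted.append(
            {
                "family": fam_id,
                "phenotype": effect.phenotype,
                "fold_change": effect.fold_change,
                "direction": effect.direction,
                "carriers": carriers,
            }
        )

    totals = counts.sum(axis=1).astype(float)
    sd_tot = float(np.std(totals, ddof=1))
    if sd_tot == 0:
        raise ValueError("degenerate panel: all genomes have identical totals")
    r2 = config.target_r2
    noise_sd = config.genome_size_slope * sd_tot * math.sqrt((1.0 - r2) / r2)
    sizes = (
        config.genome_size_base
        + config.genome_size_slope * totals
        + rng.normal(0.0, noise_sd, size=config.n_strains)
    )
    sizes = np.maximum(sizes, 5e5).round()

    meta = pd.DataFrame(
        {
            "genus": [genera[g] for g in genus_of],
            "phylum": [phyla[phylum_of_genus[g]] for g in genus_of],
            "genome_size_bp": sizes.astype(int),
        },
        index=pd.Index(strains, name="strain_id"),
    )
    counts_df = pd.DataFrame(counts, index=meta.index, columns=families)
    # drop families absent everywhere, mirroring the aggregation contract
    present = counts_df.sum(axis=0) > 0
    counts_df = counts_df.loc[:, present]
    table = GenomeCazymeTable(counts_df, meta)

    gene_lists: dict[str, list] = {}
    for si, strain in enumerate(strains):
        genes = []
        g = 0
        for fam in counts_df.columns:
            for _ in range(int(counts_df.at[strain, fam])):
                genes.append((f"{strain}_g{g + 1:05d}", (fam,)))
                g += 1
        gene_lists[strain] = genes

    return ReferencePanel(
        table=table, gene_lists=gene_lists, planted=planted, config=config
    )


@dataclass
class Cohort:
    """A simulated paired oral/gut cohort with its ground truth."""

    profile: TaxonomicProfile
    metadata: pd.DataFrame
    truth: GroundTruth
    site_pools: dict


def simulate_cohort(config: SimulationConfig, panel: ReferencePanel) -> Cohort:
    """Draw the paired-sample cohort over site-specific strain pools.

    Each subject contributes one oral and one gut sample.  The gut and
    oral pools share ``site_overlap`` of the strains; planted carrier
    strains are forced into the gut pool.  Per sample, abundances over
    the site pool are ``exp(Normal(mu_log, sigma_log))`` renormalised to
    sum to one; planted effects multiply carrier abundances in affected
    subjects by the fold change (inverted for depletions) before the
    renormalisation.  Read depths are log-uniform.
    """
    rng = config.rng(1)
    strains = list(panel.table.strains)
    n = len(strains)
    carriers_all = sorted(
        {c for eff in panel.planted for c in eff["carriers"]},
        key=strains.index,
    )

    order = list(rng.permutation(n))
    # carriers first so they land in the gut pool
    order = [strains.index(c) for c in carriers_all] + [
        i for i in order if strains[i] not in carriers_all
    ]
    n_shared = int(round(config.site_overlap * n))
    n_rest = n - n_shared
    n_gut_only = n_rest // 2 + n_rest % 2
    gut_pool = [strains[i] for i in order[:n_gut_only] + order[n_rest:]]
    oral_pool = [strains[i] for i in order[n_gut_only:n_rest] + order[n_rest:]]
    if not oral_pool or not gut_pool:
        raise ValueError("site pools are empty; increase n_strains")
    pools = {"gut": gut_pool, "oral": oral_pool}

    multiplier: dict[str, dict[str, float]] = {}
    for eff in panel.planted:
        if not eff["carriers"]:
            raise ValueError(
                f"planted family {eff['family']!r} has no carrier strains"
            )
        m = eff["fold_change"] if eff["direction"] == "enriched" else 1.0 / eff["fold_change"]
        per = multiplier.setdefault(eff["phenotype"], {})
        for c in eff["carriers"]:
            per[c] = per.get(c, 1.0) * m

    rows = []
    meta_rows = []
    read_depths = []
    sample_ids = []
    lo, hi = config.depth_range
    subj = 0
    for phenotype in config.phenotypes:
        for _ in range(config.n_subjects_per_phenotype):
            subj += 1
            subject_id = f"subj{subj:03d}"
            for site in ("oral", "gut"):
                pool = pools[site]
                raw = np.exp(rng.normal(config.mu_log, config.sigma_log, len(pool)))
                per = multiplier.get(phenotype)
                if per:
                    for ci, strain in enumerate(pool):
                        if strain in per:
                            raw[ci] *= per[strain]
                comp = raw / raw.sum()
                row = pd.Series(0.0, index=strains)
                row[pool] = comp
                rows.append(row)
                depth = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                read_depths.append(max(int(round(depth)), 1))
                sample_id = f"{subject_id}_{site}"
                sample_ids.append(sample_id)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": subject_id,
                        "body_site": site,
                        "phenotype": phenotype,
                    }
                )

    abundances = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    profile = TaxonomicProfile(
        abundances, pd.Series(read_depths, index=abundances.index, dtype=float)
    )
    metadata = validate_metadata(
        pd.DataFrame(meta_rows).set_index("sample_id")
    )

    truth = GroundTruth(
        effects=[dict(e) for e in panel.planted],
        gene_lists=panel.gene_lists,
        decoys={},
    )
    _record_achieved_fold_changes(truth, panel, profile, metadata)
    return Cohort(profile=profile, metadata=metadata, truth=truth, site_pools=pools)


def _record_achieved_fold_changes(
    truth: GroundTruth,
    panel: ReferencePanel,
    profile: TaxonomicProfile,
    metadata: pd.DataFrame,
) -> None:
    """Realized population log2 fold change of each planted family,
    depth-free (R @ N), affected gut samples vs control gut samples."""
    n = panel.table.counts.to_numpy(float)
    r = profile.abundances.reindex(columns=panel.table.strains, fill_value=0.0)
    projected = pd.DataFrame(
        r.to_numpy() @ n, index=profile.samples, columns=panel.table.families
    )
    gut = metadata["body_site"] == "gut"
    control = metadata["phenotype"] == "control"
    for eff in truth.effects:
        fam = eff["family"]
        affected = metadata["phenotype"] == eff["phenotype"]
        mean_aff = projected.loc[gut & affected, fam].mean()
        mean_ctl = projected.loc[gut & control, fam].mean()
        if mean_aff > 0 and mean_ctl > 0:
            eff["achieved_log2fc"] = float(np.log2(mean_aff / mean_ctl))
        else:
            eff["achieved_log2fc"] = float("nan")


# --------------------------------------------------------------------------
# fixture files
# --------------------------------------------------------------------------

OVERVIEW_HEADER = "Gene ID\tHMMER\tHotpep\tDIAMOND\t#ofTools"


def write_fixtures(
    panel: ReferencePanel,
    outdir: str | Path,
    decoy_fraction: float | None = None,
    truth: GroundTruth | None = None,
) -> Path:
    """Write one dbCAN2-style overview file per strain plus a manifest TSV.

    Every retained gene appears with two tool calls (Hotpep with a
    peptide-hit annotation, DIAMOND plain); occasional subfamily suffixes
    exercise canonicalisation without changing family counts.  Decoy genes
    carry exactly one tool call and must be dropped by the consensus
    filter.  Returns the manifest path.
    """
    rng = panel.config.rng(2)
    if decoy_fraction is None:
        decoy_fraction = panel.config.decoy_fraction
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = list(panel.table.families)
    manifest_rows = []
    decoys: dict[str, int] = {}
    for strain in panel.table.strains:
        genes = panel.gene_lists.get(strain, [])
        lines = [OVERVIEW_HEADER]
        for gene_id, fams in genes:
            calls = []
            for fam in fams:
                token = fam
                if rng.random() < 0.25:
                    token = f"{fam}_{rng.integers(1, 30)}"  # subfamily suffix
                calls.append(token)
            joined = "+".join(calls)
            hotpep = "+".join(f"{c}({rng.integers(3, 40)})" for c in calls)
            lines.append(f"{gene_id}\t-\t{hotpep}\t{joined}\t2")
        n_decoy = int(round(decoy_fraction * len(genes)))
        for d in range(n_decoy):
            fam = families[int(rng.integers(0, len(families)))]
            tool_cells = ["-", "-", "-"]
            tool_cells[int(rng.integers(0, 3))] = fam
            lines.append(
                f"{strain}_decoy{d + 1:04d}\t" + "\t".join(tool_cells) + "\t1"
            )
        decoys[str(strain)] = n_decoy
        fname = f"{strain}.overview.txt"
        (outdir / fname).write_text("\n".join(lines) + "\n")
        meta = panel.table.meta.loc[strain]
        manifest_rows.append(
            {
                "strain_id": strain,
                "file": fname,
                "genus": meta["genus"],
                "phylum": meta["phylum"],
                "genome_size_bp": int(meta["genome_size_bp"]),
            }
        )
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    if truth is not None:
        truth.decoys = decoys
    return manifest_path


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def score_calls(
    marker_families: Sequence[str] | set,
    truth: GroundTruth,
    contrast: str,
) -> dict:
    """Sensitivity, observed FDR and confusion counts for one contrast.

    ``sensitivity = |planted AND called| / |planted|``; ``FDR =
    |called \\ planted| / |called|`` (0 when nothing is called).
    """
    known = {f"{e['phenotype']}_vs_control" for e in truth.effects}
    if contrast not in known:
        raise KeyError(
            f"unknown contrast {contrast!r}; ground truth covers {sorted(known)}"
        )
    planted = truth.planted_families(contrast)
    called = set(marker_families)
    tp = len(planted & called)
    fp = len(called - planted)
    fn = len(planted - called)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = fp / len(called) if called else 0.0
    return {
        "contrast": contrast,
        "sensitivity": sensitivity,
        "observed_fdr": fdr,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_called": len(called),
        "n_planted": len(planted),
    }
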