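"""Projecting genome CAZyme repertoires onto metagenome taxonomic profiles.

The abundance of family ``C`` carried by strain ``S`` in metagenome ``M`` is

    AC_strain = N * R * T

with ``N`` the gene copies of ``C`` in the genome of ``S``, ``R`` the
relative abundance of ``S`` in ``M`` and ``T`` the total bacteria-associated
reads of ``M``.  Per-sample family abundance aggregates the panel either as
a per-panel-strain mean (``panel_mean``, dividing by the panel size ``P``)
or a plain sum (``sum``); the two differ by the constant factor ``P`` and
leave every standardized or count-model result downstream unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomeCazymeTable

DivisorMode = Literal["panel_mean", "sum"]

BODY_SITES = ("oral", "gut")
PHENOTYPES = ("control", "CRC", "T1D", "RA")


class TaxonomicProfile:
    """Sample x strain relative-abundance matrix plus per-sample read totals.

    Abundances are fractions in [0, 1]; each sample row sums to at most
    1 + 1e-6; total reads are positive.
    """

    def __init__(self, abundances: pd.DataFrame, total_reads: pd.Series):
        ab = abundances.astype(float)
        if (ab.to_numpy() < 0).any() or (ab.to_numpy() > 1 + 1e-9).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        row_sums = ab.sum(axis=1)
        bad = row_sums[row_sums > 1 + 1e-6]
        if len(bad):
            raise ValueError(f"sample rows exceed total abundance 1: {list(bad.index)}")
        reads = total_reads.reindex(ab.index)
        if reads.isna().any():
            raise ValueError("every sample needs a total-read count")
        if (reads <= 0).any():
            bad = list(reads.index[reads <= 0])
            raise ValueError(f"non-positive total reads for samples: {bad}")
        self.abundances = ab
        self.total_reads = reads.astype(float)

    @property
    def samples(self) -> pd.Index:
        return self.abundances.index

    @property
    def strains(self) -> pd.Index:
        return self.abundances.columns

    def to_tsv(self, abundance_path: str | Path, reads_path: str | Path) -> None:
        self.abundances.to_csv(abundance_path, sep="\t", index_label="sample_id")
        self.total_reads.rename("total_reads").to_csv(
            reads_path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def from_tsv(
        cls, abundance_path: str | Path, reads_path: str | Path
    ) -> "TaxonomicProfile":
        ab = pd.read_csv(abundance_path, sep="\t", index_col="sample_id")
        reads = pd.read_csv(reads_path, sep="\t", index_col="sample_id")["total_reads"]
        return cls(ab, reads)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (sample_id index; subject_id,
    body_site, phenotype columns).

    Each subject may contribute at most one sample per body site and must
    have a constant phenotype.
    """
    required = {"subject_id", "body_site", "phenotype"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_site = set(meta["body_site"]) - set(BODY_SITES)
    if bad_site:
        raise ValueError(f"unknown body sites: {sorted(bad_site)}")
    bad_ph = set(meta["phenotype"]) - set(PHENOTYPES)
    if bad_ph:
        raise ValueError(f"unknown phenotypes: {sorted(bad_ph)}")
    dup = meta.groupby(["subject_id", "body_site"]).size()
    if (dup > 1).any():
        raise ValueError(
            f"subjects with more than one sample per site: {list(dup[dup > 1].index)}"
        )
    n_ph = meta.groupby("subject_id")["phenotype"].nunique()
    if (n_ph > 1).any():
        raise ValueError(
            f"subjects with inconsistent phenotype: {list(n_ph[n_ph > 1].index)}"
        )
    return meta


@dataclass
class CazymeAbundanceMatrix:
    """Sample x family projected CAZyme abundances (read-count scale)."""

    values: pd.DataFrame
    divisor_mode: DivisorMode = "panel_mean"
    panel_size: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def families(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def project_strain(n_copies: float, rel_abundance: float, total_reads: float) -> float:
    """Family abundance contributed by one strain in one metagenome:
    ``N * R * T`` exactly."""
    if n_copies < 0:
        raise ValueError("gene copies must be non-negative")
    if not 0 <= rel_abundance <= 1:
        raise ValueError("relative abundance must lie in [0, 1]")
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    return float(n_copies) * float(rel_abundance) * float(total_reads)


def project_sample(
    strain_contributions: Sequence[float], divisor_mode: DivisorMode = "panel_mean"
) -> float:
    """Aggregate per-strain contributions over the reference panel.

    ``panel_mean`` divides the sum by the panel size P; ``sum`` returns the
    plain sum.  The two differ by the constant factor P.
    """
    contributions = np.asarray(strain_contributions, dtype=float)
    if contributions.size == 0:
        raise ValueError("empty strain panel")
    total = float(contributions.sum())
    if divisor_mode == "panel_mean":
        return total / contributions.size
    if divisor_mode == "sum":
        return total
    raise ValueError(f"unknown divisor mode: {divisor_mode!r}")


def build_abundance_matrix(
    genome_table: GenomeCazymeTable,
    profile: TaxonomicProfile,
    divisor_mode: DivisorMode = "panel_mean",
) -> CazymeAbundanceMatrix:
    """Project the whole panel onto every sample.

    The panel is the genome table's strain set.  Strains present in the
    profile but absent from the genome table are an error; panel strains a
    sample lacks contribute with R = 0 (absence = undetected).  The result
    is linear in R and in T.
    """
    unknown = [s for s in profile.strains if s not in genome_table.strains]
    if unknown:
        raise KeyError(f"profile strains missing from the genome table: {unknown}")
    panel = genome_table.strains
    r = profile.abundances.reindex(columns=panel, fill_value=0.0)
    n = genome_table.counts.loc[panel]
    t = profile.total_reads.to_numpy()[:, None]
    values = pd.DataFrame(
        r.to_numpy() @ n.to_numpy(float) * t,
        index=profile.samples,
        columns=genome_table.families,
    )
    p = len(panel)
    if divisor_mode == "panel_mean":
        values = values / p
    elif divisor_mode != "sum":
        raise ValueError(f"unknown divisor mode: {divisor_mode!r}")
    return CazymeAbundanceMatrix(
        values=values,
        divisor_mode=divisor_mode,
        panel_size=p,
        provenance={"divisor_mode": divisor_mode, "panel_size": p},
    )
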