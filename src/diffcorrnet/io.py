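"""File formats, run configuration and the end-to-end pipeline runner.

Concentration tables are delimited text (comma or tab, auto-detected) with a
header row, samples as rows and metabolites as columns; an empty cell means
missing and the token ``<LOD`` means below the limit of detection.
Phenotype tables carry one row per sample with WOMAC baseline/follow-up
scores and joint type.  All numeric output is written at six significant
digits so repeated runs diff cleanly; every artifact records the seed and a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffcorr import EDGE_COLUMNS
from .network import build_network, export_edgelist, export_graphml, overlap
from .permutation import PermutationConfig, permutation_test
from .phenotype import OutcomeRecord, ResponderLabels, classify, cohort_summary
from .preprocessing import (
    BELOW_LOD,
    MISSING,
    OBSERVED,
    ConcentrationMatrix,
    preprocess,
)

logger = logging.getLogger(__name__)

LOD_TOKEN = "<LOD"
FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    concentrations: str
    phenotypes: str
    output_dir: str
    lod_threshold: float = 0.10
    outlier_k: float = 3.0
    mcid_pain: int = 7
    mcid_function: int = 22
    n_permutations: int = 1000
    alpha_primary: float = 0.01
    alpha_exploratory: float = 0.05
    seed: int = 0
    outcomes: tuple = ("pain", "function")

    def __post_init__(self) -> None:
        if not 0.0 <= self.lod_threshold <= 1.0:
            raise ValueError("lod_threshold must be in [0, 1]")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if not 0.0 < self.alpha_primary < 1.0 or not 0.0 < self.alpha_exploratory < 1.0:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.outcomes = tuple(self.outcomes)
        for outcome in self.outcomes:
            if outcome not in ("pain", "function"):
                raise ValueError(f"unknown outcome {outcome!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_concentrations(path) -> ConcentrationMatrix:
    """Read a raw concentration table; map ``<LOD`` and empty cells to masks."""
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    values = np.empty(frame.shape, dtype=float)
    prov = np.full(frame.shape, OBSERVED, dtype=np.int8)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j].strip()
            if cell == "":
                values[i, j], prov[i, j] = np.nan, MISSING
            elif cell == LOD_TOKEN:
                values[i, j], prov[i, j] = np.nan, BELOW_LOD
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at sample "
                        f"{frame.index[i]!r}, metabolite {frame.columns[j]!r}"
                    ) from None
    return ConcentrationMatrix(
        pd.DataFrame(values, index=frame.index, columns=frame.columns),
        pd.DataFrame(prov, index=frame.index, columns=frame.columns),
        "raw",
    )


def write_concentrations(matrix: ConcentrationMatrix, path, sep: str = "\t") -> None:
    """Write a raw-stage matrix; below-LOD cells as ``<LOD``, missing as empty."""
    out = matrix.values.map(lambda v: "" if pd.isna(v) else FLOAT_FMT % v)
    lod = matrix.provenance == BELOW_LOD
    out = out.mask(lod, LOD_TOKEN)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


_PHENO_COLS = [
    "sample_id", "baseline_pain", "followup_pain",
    "baseline_function", "followup_function", "joint", "primary_oa",
]


def read_phenotypes(path) -> list[OutcomeRecord]:
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")

    def _score(cell: str, where: str) -> int | None:
        cell = cell.strip()
        if cell == "":
            return None
        try:
            return int(float(cell))
        except ValueError:
            raise ValueError(f"non-numeric score {cell!r} at {where}") from None

    records = []
    for row in frame.itertuples(index=False):
        records.append(
            OutcomeRecord(
                sample_id=row.sample_id,
                baseline_pain=_score(row.baseline_pain, f"{row.sample_id}/baseline_pain"),
                followup_pain=_score(row.followup_pain, f"{row.sample_id}/followup_pain"),
                baseline_function=_score(row.baseline_function, f"{row.sample_id}/baseline_function"),
                followup_function=_score(row.followup_function, f"{row.sample_id}/followup_function"),
                joint=getattr(row, "joint", "unknown") or "unknown",
                primary_oa=str(getattr(row, "primary_oa", "True")).lower()
                not in ("false", "0", "no"),
            )
        )
    return records


def write_phenotypes(records: list[OutcomeRecord], path, sep: str = "\t") -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "sample_id": rec.sample_id,
                "baseline_pain": "" if rec.baseline_pain is None else rec.baseline_pain,
                "followup_pain": "" if rec.followup_pain is None else rec.followup_pain,
                "baseline_function": "" if rec.baseline_function is None else rec.baseline_function,
                "followup_function": "" if rec.followup_function is None else rec.followup_function,
                "joint": rec.joint,
                "primary_oa": rec.primary_oa,
            }
        )
    pd.DataFrame(rows, columns=_PHENO_COLS).to_csv(path, sep=sep, index=False)


def write_edge_table(edges: pd.DataFrame, path, sep: str = "\t") -> None:
    edges.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_edge_table(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep)


def write_labels(labels: ResponderLabels, path, sep: str = "\t") -> None:
    labels.frame.to_csv(path, sep=sep)


def run_pipeline(config: RunConfig) -> dict:
    """Execute QC -> classification -> differential correlation -> permutation
    -> network for every selected outcome; write all artifacts; return the
    run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = read_concentrations(config.concentrations)
    records = read_phenotypes(config.phenotypes)
    normalized, qc = preprocess(matrix, config.lod_threshold, config.outlier_k)
    labels = classify(records, config.mcid_pain, config.mcid_function)
    summary = cohort_summary(labels, records)

    write_labels(labels, outdir / "labels.tsv")
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc.to_dict(), fh, indent=2)

    seed_rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "diffcorrnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "qc": qc.to_dict(),
        "cohort": summary,
        "outcomes": {},
        "notes": "No multiple-testing correction applied beyond the fixed "
                 "significance thresholds; outlier exclusion masks individual "
                 "cells, not whole samples.",
    }

    networks = {}
    for outcome in config.outcomes:
        perm_seed = int(seed_rng.integers(0, 2**31 - 1))
        pconfig = PermutationConfig(
            n_permutations=config.n_permutations,
            seed=perm_seed,
            alpha=config.alpha_primary,
        )
        result = permutation_test(normalized, labels, outcome, pconfig)
        write_edge_table(result.edges, outdir / f"edges_{outcome}.tsv")
        entry = {"permutation_seed": perm_seed, "n_pairs": len(result.edges)}
        for alpha, tag in (
            (config.alpha_primary, "primary"),
            (config.alpha_exploratory, "exploratory"),
        ):
            net = build_network(result.edges, alpha)
            stem = f"network_{outcome}_{tag}"
            export_graphml(net, outdir / f"{stem}.graphml")
            export_edgelist(net, outdir / f"{stem}_edges.tsv")
            entry[tag] = {
                "alpha": alpha,
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "component_sizes": net.component_sizes,
            }
            if tag == "primary":
                networks[outcome] = net
        manifest["outcomes"][outcome] = entry

    if len(networks) == 2:
        rep = overlap(networks["pain"], networks["function"])
        pd.DataFrame(
            rep.shared_edges, columns=["metabolite_i", "metabolite_j", "sign"]
        ).to_csv(outdir / "overlap_edges.tsv", sep="\t", index=False)
        manifest["overlap"] = {
            "shared_nodes": sorted(rep.shared_nodes),
            "n_shared_edges": len(rep.shared_edges),
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
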