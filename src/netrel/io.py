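"""Delimited-text readers and writers for the pipeline's objects.

Everything is plain TSV or JSON: time series as time x node matrices with a
node-label header, square matrices with a label header, filtered graphs as
3-column edge lists, cohorts as one TSV per scan plus a JSON manifest,
measurement tables and ICC tables as tidy TSVs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDesign, CohortTimeseries
from .graphs import FilteredGraph, edge_list
from .reliability import ICCResult

__all__ = [
    "write_timeseries", "read_timeseries", "write_matrix", "read_matrix",
    "write_edge_list", "read_edge_list", "write_cohort", "read_cohort",
    "write_measurement_table", "read_measurement_table",
    "write_band_table", "icc_result_to_dict",
]


def write_timeseries(path, ts: np.ndarray, labels: list[str]) -> None:
    """Write a node x time matrix as time x node TSV with a label header."""
    pd.DataFrame(np.asarray(ts).T, columns=labels).to_csv(path, sep="\t", index=False)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T, list(df.columns)


def write_matrix(path, mat: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(np.asarray(mat), columns=labels).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_edge_list(path, G: FilteredGraph) -> None:
    rows = [(G.labels[i], G.labels[j], w) for i, j, w in edge_list(G.adj)]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, sep="\t", index=False)


def read_edge_list(path, labels: list[str] | None = None) -> FilteredGraph:
    df = pd.read_csv(path, sep="\t")
    if labels is None:
        labels = sorted(set(df["node_i"]) | set(df["node_j"]))
    idx = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)))
    for _, row in df.iterrows():
        i, j = idx[row["node_i"]], idx[row["node_j"]]
        adj[i, j] = adj[j, i] = float(row["weight"])
    return FilteredGraph(adj=adj, labels=list(labels))


def write_band_table(path, bands) -> None:
    pd.DataFrame([{"name": b.name, "f_low": b.f_low, "f_high": b.f_high,
                   "theoretical_low": b.theoretical_low,
                   "theoretical_high": b.theoretical_high} for b in bands]
                 ).to_csv(path, sep="\t", index=False)


def write_cohort(cohort: CohortTimeseries, out_dir) -> Path:
    """Write one TSV per scan plus a JSON manifest (design, covariates, files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for (k, j, i) in cohort.keys():
        name = f"sub-{k:03d}_visit-{j}_meas-{i}.tsv"
        write_timeseries(out / name, cohort[(k, j, i)], cohort.labels)
        files[f"{k},{j},{i}"] = name
    manifest = {
        "tr": cohort.tr,
        "labels": cohort.labels,
        "design": dataclasses.asdict(cohort.design) if cohort.design else None,
        "covariates": cohort.covariates.to_dict(orient="list"),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(in_dir) -> CohortTimeseries:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    scans = {}
    for key, name in manifest["files"].items():
        k, j, i = (int(x) for x in key.split(","))
        ts, _ = read_timeseries(root / name)
        scans[(k, j, i)] = ts
    design = CohortDesign(**manifest["design"]) if manifest["design"] else None
    return CohortTimeseries(scans=scans, tr=manifest["tr"],
                            covariates=pd.DataFrame(manifest["covariates"]),
                            design=design, labels=list(manifest["labels"]))


def write_measurement_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_measurement_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def icc_result_to_dict(res: ICCResult) -> dict:
    out = {"icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
           "level": res.level, "vb": res.vb, "vw": res.vw, "flags": res.flags}
    if res.fit is not None:
        out["variance_components"] = {
            "sigma2_subject": res.fit.sigma2_subject,
            "sigma2_visit": res.fit.sigma2_visit,
            "sigma2_residual": res.fit.sigma2_residual,
            "gamma000": res.fit.gamma000,
            "slopes": res.fit.slopes,
            "method": res.fit.method,
            "converged": res.fit.converged,
        }
    return out
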