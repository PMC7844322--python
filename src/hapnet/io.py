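"""File formats: TSV DAG/allele tables, CSV phenotypes and posteriors,
YAML run configs, JSON run metadata."""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import AlleleMatrix, HaplotypeDAG, parse_dag, write_dag
from .simulate import SimulatedDataset

__all__ = [
    "read_allele_matrix",
    "write_allele_matrix",
    "write_dataset",
    "read_dataset",
    "load_config",
    "write_run_metadata",
]


def read_allele_matrix(path) -> AlleleMatrix:
    """TSV: first column haplotype id, remaining columns sites, values 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AlleleMatrix(df.to_numpy(dtype=np.int8),
                        [str(c) for c in df.columns],
                        [str(i) for i in df.index])


def write_allele_matrix(am: AlleleMatrix, path) -> None:
    df = am.to_frame()
    df.index.name = "haplotype"
    df.to_csv(path, sep="\t")


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write dag.tsv, alleles.tsv, phenotypes.csv, truth.csv, meta.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_dag(ds.dag, out / "dag.tsv")
    if ds.U is not None:
        write_allele_matrix(ds.U, out / "alleles.tsv")

    hap_of_ind = [ds.haplotype_ids[j] for j in np.argmax(ds.Z, axis=1)]
    pd.DataFrame({
        "individual": [f"ind{i:04d}" for i in range(len(ds.y))],
        "phenotype": ds.y,
        "haplotype": hap_of_ind,
    }).to_csv(out / "phenotypes.csv", index=False)

    truth = pd.DataFrame({"id": ds.haplotype_ids, "kind": "haplotype",
                          "value": ds.true_h})
    if ds.true_v is not None:
        truth = pd.concat([truth, pd.DataFrame({
            "id": ds.U.site_ids, "kind": "mutation", "value": ds.true_v,
        })], ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False)

    write_run_metadata(out / "meta.json", command="simulate",
                       seed=ds.seed, scenario=ds.scenario, params=ds.params)


def read_dataset(indir):
    """Read back a simulated dataset directory (dag, alleles, phenotypes)."""
    indir = Path(indir)
    dag = parse_dag(indir / "dag.tsv")
    am = None
    if (indir / "alleles.tsv").exists():
        am = read_allele_matrix(indir / "alleles.tsv")
    pheno = pd.read_csv(indir / "phenotypes.csv")
    named = [n for n in dag.topo_order if not dag.is_phantom[n]]
    pos = {h: j for j, h in enumerate(named)}
    Z = np.zeros((len(pheno), len(named)))
    for i, h in enumerate(pheno["haplotype"].astype(str)):
        if h not in pos:
            raise ValueError(f"phenotypes.csv line {i + 2}: haplotype {h!r} "
                             "is not a DAG node")
        Z[i, pos[h]] = 1.0
    return dag, am, named, pheno["phenotype"].to_numpy(dtype=float), Z


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path}: expected a YAML mapping")
    return cfg


def write_run_metadata(path, **fields) -> None:
    meta = {
        "package": "hapnet",
        "python": sys.version.split()[0],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **{k: _jsonable(v) for k, v in fields.items()},
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, np.random.SeedSequence):
        return v.entropy
    return v
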