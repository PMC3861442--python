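"""Ensemble and diagram readers/writers (TSV + YAML manifest)."""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import Ensemble, Trajectory

__all__ = ["write_ensemble", "read_ensemble", "read_diagram_edges"]


class _IOLayout:
    """Minimal layout reconstructed from a manifest (locus -> gene map)."""

    def __init__(self, gene_names, locus_genes, locus_alleles):
        self.gene_names = tuple(gene_names)
        self.locus_gene = np.asarray(
            [self.gene_names.index(g) for g in locus_genes], dtype=np.int32
        )
        self.locus_allele = np.asarray(locus_alleles, dtype=np.int32)


def write_ensemble(ensemble: Ensemble, outdir: str | Path) -> Path:
    """One TSV per cell plus a manifest describing the layout."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = ensemble.trajectories[0]
    lay = t0.layout
    manifest = {
        "n_cells": ensemble.n_cells,
        "duration_s": float(ensemble.duration),
        "culture_mode": ensemble.culture_mode,
        "params_hash": ensemble.params_hash,
        "gene_names": list(t0.gene_names),
        "locus_genes": [
            t0.gene_names[lay.locus_gene[li]] for li in range(t0.ta.shape[1])
        ],
        "locus_alleles": [int(a) for a in lay.locus_allele],
        "cells": [f"cell_{i:05d}.tsv" for i in range(ensemble.n_cells)],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    for name, traj in zip(manifest["cells"], ensemble.trajectories):
        traj.write_tsv(out / name)
    return out / "manifest.yaml"


def read_ensemble(path: str | Path) -> Ensemble:
    d = Path(path)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    genes = tuple(manifest["gene_names"])
    lay = _IOLayout(genes, manifest["locus_genes"], manifest["locus_alleles"])
    tags = [
        f"{g}.{a}" for g, a in zip(manifest["locus_genes"], manifest["locus_alleles"])
    ]
    trajs = []
    for name in manifest["cells"]:
        df = pd.read_csv(d / name, sep="\t")
        counts = np.stack([df[f"n_{g}"].to_numpy(np.int64) for g in genes], axis=1)
        ta = np.stack(
            [(df[f"ta_{t}"].to_numpy(float) * 2).astype(np.int8) for t in tags], axis=1
        )
        hist = np.stack(
            [df[f"hist_{t}"].to_numpy(np.int8) for t in tags], axis=1
        )
        bnd = np.stack(
            [df[f"bound_{t}"].to_numpy(np.uint8) for t in tags], axis=1
        )
        trajs.append(
            Trajectory(
                times=df["time_s"].to_numpy(float),
                counts=counts, ta=ta, hist=hist, bound_mask=bnd,
                gene_names=genes, seed=-1,
                params_hash=manifest["params_hash"], layout=lay,
            )
        )
    return Ensemble(
        trajectories=trajs,
        duration=manifest["duration_s"],
        culture_mode=manifest["culture_mode"],
        params_hash=manifest["params_hash"],
    )


def read_diagram_edges(prefix: str | Path):
    """Rates {(i, j): W} from a diagram edge table written by the CLI."""
    df = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")

    def parse(v):
        try:
            return ast.literal_eval(v) if isinstance(v, str) else v
        except (SyntaxError, ValueError):
            return v

    return {
        (parse(r["from"]), parse(r["to"])): float(r["rate_per_day"])
        for _, r in df.iterrows()
    }
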