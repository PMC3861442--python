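"""Deterministic fixtures for testing the simulator and the analyses.

Three kinds:

``toy-telegraph``
    A single isolated locus whose transcription apparatus cycles
    0 -> 1/2 -> 1 -> 0 with known rates (histone frozen active, no binding
    sites), so state occupancies have a closed form.
``toy-two-gene``
    Two mutually repressing genes (a genetic toggle) as a network config.
``looped-diamond``
    A four-state, five-edge transition diagram containing two independent
    loops, with synthetic bidirectional rates, for the landscape solver.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import GeneSpec, ParameterSet, RegulatoryNetwork

__all__ = [
    "single_gene_network",
    "single_gene_params",
    "toggle_network",
    "looped_diamond_rates",
    "telegraph_occupancies",
    "make_fixture",
]


def single_gene_network(n_alleles: int = 1) -> RegulatoryNetwork:
    """One isolated locus, no binding sites, no feedback."""
    return RegulatoryNetwork((GeneSpec("G", (), (), n_alleles=n_alleles),))


def single_gene_params(
    g: float = 0.05,
    b: float = 1.0,
    k: float = 1e-3,
    kf1: float = 0.0,
    kf2: float = 0.0,
    kdiss: float = 0.0,
    gamma: float = 5.0,
) -> ParameterSet:
    """Parameters for the isolated locus.

    With the zero defaults for the TA rates the apparatus is frozen, giving
    a pure bursty birth-death process; finite rates turn it into the
    three-state TA cycle with basal formation (nothing is ever bound).
    """
    return ParameterSet(
        g_full=g, gamma_synth=gamma, b_mean=b, k_deg=k,
        h0_bind=0.0, f_unbind=1.0, K_dimer=0.0,
        k_ta_form1=kf1, k_ta_form1_basal=kf1, k_ta_form1_rep=0.0,
        k_ta_form2=kf2, k_ta_diss=kdiss,
        r_on=0.0, r_on_basal=0.0, r_off=0.0,
    )


def telegraph_occupancies(kf1: float, kf2: float, kdiss: float) -> tuple[float, float, float]:
    """Stationary occupancies (p0, p_half, p1) of the TA cycle.

    The cycle 0 -> 1/2 (kf1), 1/2 -> 1 (kf2), 1/2 -> 0 and 1 -> 0 (kdiss)
    is a three-state Markov chain; the closed form follows from balancing
    the stationary fluxes.
    """
    # p0 * kf1 = p_half * (kf2 + kdiss);  p1 * kdiss = p_half * kf2
    ph_over_p0 = kf1 / (kf2 + kdiss)
    p1_over_ph = kf2 / kdiss
    z = 1.0 + ph_over_p0 * (1.0 + p1_over_ph)
    p0 = 1.0 / z
    ph = p0 * ph_over_p0
    return p0, ph, ph * p1_over_ph


def toggle_network() -> RegulatoryNetwork:
    """Two mutually repressing, self-activating genes."""
    return RegulatoryNetwork(
        (
            GeneSpec("A", ("A",), ("B",), n_alleles=1),
            GeneSpec("B", ("B",), ("A",), n_alleles=1),
        )
    )


def looped_diamond_rates(seed: int = 0) -> dict[tuple, float]:
    """Bidirectional rates [1/day] on the 4-state, 5-edge, 2-loop graph.

    States a, b, c, d are connected a-b, b-c, c-d, d-a and across the
    diagonal a-c; the cycle basis has two independent loops.
    """
    rng = np.random.default_rng(seed)
    pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
    out = {}
    for i, j in pairs:
        out[(i, j)] = float(np.exp(rng.normal(0.0, 0.7)))
        out[(j, i)] = float(np.exp(rng.normal(0.0, 0.7)))
    return out


def make_fixture(kind: str, seed: int = 0, outdir: str | Path = ".") -> list[Path]:
    """Write a fixture to ``outdir``; returns the created paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    if kind == "toy-telegraph":
        kf1, kf2, kdiss = 2e-4, 2e-4, 2e-4
        truth = {
            "kf1": kf1, "kf2": kf2, "kdiss": kdiss,
            "occupancies": telegraph_occupancies(kf1, kf2, kdiss),
        }
        p = out / "telegraph_truth.json"
        p.write_text(json.dumps(truth, indent=1))
        paths.append(p)
    elif kind == "toy-two-gene":
        from .config import network_to_dict

        p = out / "toggle_network.yaml"
        import yaml

        p.write_text(yaml.safe_dump({"network": network_to_dict(toggle_network())}))
        paths.append(p)
    elif kind == "looped-diamond":
        rates = looped_diamond_rates(seed)
        p = out / "looped_diamond_edges.tsv"
        lines = ["from\tto\trate_per_day"]
        for (i, j), w in sorted(rates.items()):
            lines.append(f"{i}\t{j}\t{w:.10g}")
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
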