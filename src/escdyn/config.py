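"""Configuration loading and serialization (one YAML dialect).

A run is fully described by one config file: the network wiring, the rate
parameters with per-gene overrides, run settings, score thresholds, the
banding scheme and the landscape options.  The bundled default reproduces
the shipped slow-Nanog parameterization; `load_config` fills unspecified
keys from it and rejects unknown keys.  The resolved config of every CLI
run is written next to its outputs.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cellstates import GeneBands, LevelScheme
from .network import GeneSpec, ParameterSet, RegulatoryNetwork
from .scoring import ScoreThresholds

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_config_dict",
    "save_config",
    "network_to_dict",
    "network_from_dict",
]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


def default_config_dict() -> dict:
    text = resources.files("escdyn.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def network_to_dict(network: RegulatoryNetwork) -> dict:
    return {
        g.name: {
            "activators": list(g.activator_sites),
            "repressors": list(g.repressor_sites),
            "histone_complex_rule": g.histone_complex_rule,
            "secondary_oct4_repressor": g.secondary_oct4_repressor,
            "n_alleles": g.n_alleles,
        }
        for g in network.genes
    }


def network_from_dict(d: dict) -> RegulatoryNetwork:
    genes = []
    for name, spec in d.items():
        genes.append(
            GeneSpec(
                name=name,
                activator_sites=tuple(spec.get("activators", [])),
                repressor_sites=tuple(spec.get("repressors", [])),
                histone_complex_rule=bool(spec.get("histone_complex_rule", False)),
                secondary_oct4_repressor=bool(
                    spec.get("secondary_oct4_repressor", False)
                ),
                n_alleles=int(spec.get("n_alleles", 2)),
            )
        )
    return RegulatoryNetwork(tuple(genes))


def _merge(base: dict, user: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in user.items():
        here = f"{path}.{k}" if path else str(k)
        if k not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge(base[k], v, here)
        else:
            out[k] = v
    return out


# sections whose sub-keys are free-form (gene names etc.)
_FREE_SECTIONS = {"network", "gene_overrides", "bands", "axis_weights"}


def _merge_top(base: dict, user: dict) -> dict:
    out = dict(base)
    for k, v in user.items():
        if k not in base:
            raise ConfigError(f"unknown config key: {k}")
        if k in _FREE_SECTIONS:
            out[k] = v  # replaces wholesale
        elif isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge_free(base[k], v, k)
        else:
            out[k] = v
    return out


def _merge_free(base: dict, user: dict, path: str) -> dict:
    out = dict(base)
    for k, v in user.items():
        here = f"{path}.{k}"
        if k in _FREE_SECTIONS:
            out[k] = v
            continue
        if k not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge_free(base[k], v, here)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated, fully resolved configuration."""

    raw: dict = field(repr=False)
    network: RegulatoryNetwork
    params: ParameterSet
    scheme: LevelScheme
    thresholds: ScoreThresholds

    @property
    def run(self) -> dict:
        return self.raw["run"]

    @property
    def scan(self) -> dict:
        return self.raw["scan"]

    @property
    def coarse(self) -> dict:
        return self.raw["coarse_grain"]

    @property
    def landscape(self) -> dict:
        return self.raw["landscape"]


def _build(raw: dict) -> RunConfig:
    if int(raw.get("version", CONFIG_VERSION)) != CONFIG_VERSION:
        raise ConfigError(f"unsupported config version {raw.get('version')}")
    network = network_from_dict(raw["network"])
    p = raw["parameters"]
    params = ParameterSet(
        g_full=float(p["g_full"]),
        gamma_synth=float(p["gamma_synth"]),
        b_mean=float(p["b_mean"]),
        k_deg=float(p["k_deg"]),
        h0_bind=float(p["h0_bind"]),
        f_unbind=float(p["f_unbind"]),
        K_dimer=float(p["K_dimer"]),
        k_ta_form1=float(p["k_ta_form1"]),
        k_ta_form1_basal=float(p["k_ta_form1_basal"]),
        k_ta_form1_rep=float(p["k_ta_form1_rep"]),
        k_ta_form2=float(p["k_ta_form2"]),
        k_ta_diss=float(p["k_ta_diss"]),
        r_on=float(p["r_on"]),
        r_on_basal=float(p["r_on_basal"]),
        r_off=float(p["r_off"]),
        culture_mode=str(raw["run"]["mode"]),
        oct4_synth_factor=float(raw["run"]["oct4_synth_factor"]),
        gene_overrides={
            g: {k: float(v) for k, v in ov.items()}
            for g, ov in (p.get("gene_overrides") or {}).items()
        },
    )
    neg = [k for k, v in p.items() if isinstance(v, (int, float)) and v < 0]
    if neg:
        raise ConfigError(f"negative rate(s) in parameters: {', '.join(neg)}")
    cg = raw["coarse_grain"]
    bands = {
        g: GeneBands(
            edges=tuple(b["edges"]),
            names=tuple(b["names"]),
            lambdas=tuple(b["lambdas"]),
        )
        for g, b in cg["bands"].items()
    }
    scheme = LevelScheme(bands=bands, histone_genes=tuple(cg["histone_genes"]))
    sc = raw["score"]
    thresholds = ScoreThresholds(
        peak_ratio_window=tuple(sc["peak_ratio_window"]),
        height_ratio_primary=tuple(sc["height_ratio_primary"]),
        height_ratio_secondary=tuple(sc["height_ratio_secondary"]),
        zero_fraction_max=float(sc["zero_fraction_max"]),
        smoothing_decades=float(sc["smoothing_decades"]),
        prominence_floor=float(sc["prominence_floor"]),
    )
    return RunConfig(
        raw=raw, network=network, params=params, scheme=scheme,
        thresholds=thresholds,
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a config, filling defaults from the bundled file.

    Unknown keys are rejected with their dotted path; a missing ``path``
    returns the resolved defaults.
    """
    base = default_config_dict()
    if path is None:
        return _build(base)
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        user = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {p}: {e}") from e
    if not isinstance(user, dict):
        raise ConfigError(f"top level of {p} must be a mapping")
    return _build(_merge_top(base, user))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config (version-stamped)."""
    raw = dict(cfg.raw)
    raw["version"] = CONFIG_VERSION
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
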