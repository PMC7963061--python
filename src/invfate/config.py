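"""Named parameter profiles and YAML config loading.

The base parameter table is the unscaled study system — a
Drosophila-melanogaster-like genome: N = 25,000 diploids, three 1 Mb
chromosomes with 300 kb coding each, mu = 8.4e-9, gamma DFE with shape 0.5
and mean |s| = 0.005, rho = 3.0e-8, gamma = 1.8e-8, lambda = 500 bp,
s_het = 0.003. Each named profile applies its rescaling factor to that
table: ``published`` is the Q = 10 cluster-scale configuration (the
packaged default), and the ``desk`` profiles rescale further (Q = 50) for
workstation-sized runs with correspondingly compressed generation horizons.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .experiment import ExperimentConfig
from .params import (
    ConfigurationError,
    SimulationParameters,
    build_genome_layout,
    rescale,
)

__all__ = ["PROFILES", "profile_config", "load_config"]


def _unscaled() -> SimulationParameters:
    return SimulationParameters()


# profile name -> (rescale factor, burn-in, horizon, record interval, N override)
_PROFILE_SPECS: dict[str, tuple[float, int, int, int, Optional[int]]] = {
    # the study's published scale: Q=10, run on a cluster
    "published": (10.0, 500_000, 500_000, 200, None),
    # published scale with the smaller population (N = 5,000 unscaled)
    "published-small-n": (10.0, 500_000, 500_000, 200, 500),
    # workstation scale: extra 5x rescale, compressed horizons
    "desk": (50.0, 4_000, 10_000, 200, None),
    # desk analogue of the small-population (balanced-lethal-prone) runs
    "desk-small-n": (50.0, 2_000, 10_000, 200, 100),
}


def profile_config(name: str = "published") -> ExperimentConfig:
    """Build the ExperimentConfig for a named profile."""
    if name == "unscaled":
        return ExperimentConfig(params=_unscaled())
    if name not in _PROFILE_SPECS:
        raise ConfigurationError(
            f"unknown profile {name!r}; choose from {sorted(_PROFILE_SPECS) + ['unscaled']}"
        )
    q, burn, horizon, interval, n_override = _PROFILE_SPECS[name]
    params = rescale(_unscaled(), q)
    params = replace(
        params, burn_in_gens=burn, max_gens=horizon, record_interval=interval
    )
    if n_override is not None:
        params = replace(params, N=n_override)
    return ExperimentConfig(params=params)


PROFILES = tuple(sorted(_PROFILE_SPECS) + ["unscaled"])

_PARAM_KEYS = {
    "N", "mu", "s_het", "burn_in_gens", "max_gens", "record_interval", "seed",
}
_DFE_KEYS = {"shape", "mean_s"}
_RECOMB_KEYS = {"crossover_rate", "gc_init_rate", "gc_tract_mean", "sex_halving"}
_LAYOUT_KEYS = {"coding_fraction", "segment_len", "gap_len", "chrom_len", "n_chrom"}
_CONFIG_KEYS = {
    "profile", "rescale_q", "params", "dfe", "recomb", "layout",
    "founder_mode", "replicates", "gc_grid", "s_het_grid",
    "inversion_fraction_of_genome", "co_multiplier", "snapshot_size",
    "virtual_pairs",
}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {where} key(s): {sorted(unknown)}")


def load_config(path: Union[str, Path, None] = None) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML file.

    An empty (or absent) file yields the packaged default: the published-scale profile,
    i.e. the unscaled parameter table rescaled by Q = 10. A ``profile`` key
    selects a different base; ``rescale_q`` applies an additional rescale on
    top of the profile; the remaining sections override individual fields.
    Unknown keys are rejected with the offending name.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _CONFIG_KEYS, "config")

    cfg = profile_config(str(raw.get("profile", "published")))
    params = cfg.params

    if "dfe" in raw:
        _check_keys(raw["dfe"], _DFE_KEYS, "dfe")
        params = replace(params, dfe=replace(params.dfe, **raw["dfe"]))
    if "recomb" in raw:
        _check_keys(raw["recomb"], _RECOMB_KEYS, "recomb")
        params = replace(params, recomb=replace(params.recomb, **raw["recomb"]))
    if "layout" in raw:
        _check_keys(raw["layout"], _LAYOUT_KEYS, "layout")
        params = replace(params, layout=build_genome_layout(**raw["layout"]))
    if "params" in raw:
        _check_keys(raw["params"], _PARAM_KEYS, "params")
        params = replace(params, **raw["params"])
    if "rescale_q" in raw:
        params = rescale(params, float(raw["rescale_q"]))

    kwargs = {
        k: raw[k]
        for k in (
            "founder_mode", "replicates", "gc_grid", "s_het_grid",
            "inversion_fraction_of_genome", "co_multiplier", "snapshot_size",
            "virtual_pairs",
        )
        if k in raw
    }
    return replace(cfg, params=params, **kwargs)
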