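"""Run-result persistence: TSV series/tables, JSON metadata, snapshots, VCF.

A run directory contains::

    series.tsv              one row per recorded interval
    metadata.json           fate, seed, resolved parameters, design flags
    substitutions.tsv       whole-population fixations (pruned, logged)
    arrangement_fixed.tsv   final-state within-arrangement fixations
    snapshots/snap_<gen>.sites.tsv + .matrix.tsv

``read_run_result(write_run_result(run))`` reproduces the run field for
field. The optional VCF export writes sampled snapshot haplotypes as phased
pseudo-individuals (pairs of consecutive sample rows) at the snapshot's
sites.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .experiment import RunResult
from .summaries import ArrangementSnapshot

__all__ = ["write_run_result", "read_run_result", "snapshot_to_vcf"]

_META_VERSION = 1


def _dump_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _load_df(path: Path) -> pd.DataFrame:
    if not path.exists() or path.stat().st_size == 0:
        return pd.DataFrame()
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_run_result(run: RunResult, directory: Union[str, Path]) -> Path:
    """Serialize a RunResult into ``directory`` (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    try:
        _dump_df(run.series, d / "series.tsv")
        _dump_df(run.substitutions, d / "substitutions.tsv")
        _dump_df(run.arrangement_fixed, d / "arrangement_fixed.tsv")
        meta = {
            "format_version": _META_VERSION,
            "fate": run.fate,
            "fate_gen": run.fate_gen,
            "intro_gen": run.intro_gen,
            "metadata": run.metadata,
            "snapshot_gens": [s.generation for s in run.snapshots],
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=1, default=_jsonify))
        if run.snapshots:
            sd = d / "snapshots"
            sd.mkdir(exist_ok=True)
            for snap in run.snapshots:
                _dump_df(snap.sites, sd / f"snap_{snap.generation}.sites.tsv")
                mat = pd.DataFrame(snap.matrix)
                mat.insert(0, "arrangement", snap.arrangements)
                _dump_df(mat, sd / f"snap_{snap.generation}.matrix.tsv")
    except OSError as e:
        raise OSError(f"failed writing run result under {d}: {e}") from e
    return d


def read_run_result(directory: Union[str, Path]) -> RunResult:
    """Inverse of :func:`write_run_result`."""
    d = Path(directory)
    try:
        meta = json.loads((d / "metadata.json").read_text())
    except OSError as e:
        raise OSError(f"failed reading run result under {d}: {e}") from e
    snapshots = []
    for gen in meta.get("snapshot_gens", []):
        sites = _load_df(d / "snapshots" / f"snap_{gen}.sites.tsv")
        mat = _load_df(d / "snapshots" / f"snap_{gen}.matrix.tsv")
        arrangements = mat["arrangement"].to_numpy(dtype=object)
        matrix = mat.drop(columns=["arrangement"]).to_numpy(dtype=np.uint8)
        snapshots.append(
            ArrangementSnapshot(
                matrix=matrix, arrangements=arrangements, sites=sites, generation=int(gen)
            )
        )
    return RunResult(
        series=_load_df(d / "series.tsv"),
        fate=meta["fate"],
        fate_gen=meta["fate_gen"],
        intro_gen=meta["intro_gen"],
        snapshots=snapshots,
        substitutions=_load_df(d / "substitutions.tsv"),
        arrangement_fixed=_load_df(d / "arrangement_fixed.tsv"),
        metadata=meta["metadata"],
    )


def snapshot_to_vcf(snap: ArrangementSnapshot, path: Union[str, Path]) -> Path:
    """Write snapshot haplotypes as a minimal phased VCF.

    Consecutive sample rows are paired into pseudo-individuals named
    ``<arr1><arr2>_<k>``; each site becomes one biallelic record with its
    selection coefficient and origin generation in INFO.
    """
    path = Path(path)
    n_hap = snap.n_haplotypes
    pairs = [(i, i + 1) for i in range(0, n_hap - 1, 2)]
    names = [
        f"{snap.arrangements[a]}{snap.arrangements[b]}_{k}"
        for k, (a, b) in enumerate(pairs)
    ]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient">',
        '##INFO=<ID=OG,Number=1,Type=Integer,Description="Origin generation">',
        '##INFO=<ID=RC,Number=1,Type=String,Description="Region class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = sorted(set(int(c) for c in snap.sites["chrom"]))
    for c in chroms:
        lines.append(f"##contig=<ID=chr{c + 1}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names)
    )
    for j, site in snap.sites.iterrows():
        gts = "\t".join(
            f"{snap.matrix[a, j]}|{snap.matrix[b, j]}" for a, b in pairs
        )
        info = f"S={site['s']:.6g};OG={int(site['origin_gen'])};RC={site['region_class']}"
        lines.append(
            f"chr{int(site['chrom']) + 1}\t{int(site['pos']) + 1}\t{int(site['uid'])}"
            f"\tA\tT\t.\tPASS\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
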