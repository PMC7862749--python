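"""Reading and writing count matrices, fits, and run manifests.

Count matrices are TSV/CSV: first column sample IDs, header row taxon IDs,
nonnegative integer cells.  Taxon column order is preserved exactly as read
— the model is order-sensitive — and recorded in every manifest.  Each run
directory carries a JSON manifest sufficient to re-run the exact command
(resolved parameters, seed, input checksum, package version).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import Cohort, Fit, GroundTruth, PosteriorDraws

__all__ = [
    "read_counts",
    "write_counts",
    "write_ground_truth",
    "read_ground_truth",
    "write_fit",
    "read_fit",
    "write_manifest",
    "file_checksum",
]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path, dialect: str | None = None) -> Cohort:
    """Load a sample-by-taxon count matrix (TSV by default, CSV by extension
    or ``dialect``).  Raises a format error naming the offending cell for
    negative or non-integer entries, and on duplicate sample/taxon IDs."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dup = sorted({t for t in header if header.count(t) > 1})
        raise ValueError(f"duplicate taxon IDs: {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    values = df.to_numpy()
    for d, i in np.argwhere(~(values == np.floor(values)) if values.dtype.kind == "f" else np.zeros_like(values, bool)):
        raise ValueError(f"non-integer count at sample {df.index[d]!r}, taxon {df.columns[i]!r}")
    bad = np.argwhere(values < 0)
    if bad.size:
        d, i = bad[0]
        raise ValueError(f"negative count at sample {df.index[d]!r}, taxon {df.columns[i]!r}")
    return Cohort(counts=values.astype(np.int64), sample_ids=list(df.index.astype(str)), taxon_ids=list(df.columns.astype(str)))


def write_counts(cohort: Cohort, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(cohort.counts, index=pd.Index(cohort.sample_ids, name="sample_id"), columns=cohort.taxon_ids)
    df.to_csv(path, sep=_sep_for(path, dialect))


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict[str, Any]) -> None:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"), **config}

    def _default(o: Any):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_default) + "\n")


def _write_matrix(path: Path, mat: np.ndarray, index: list[str], columns: list[str], fmt: str | None = None) -> None:
    df = pd.DataFrame(mat, index=pd.Index(index, name="id"), columns=columns)
    df.to_csv(path, sep="\t", float_format=fmt)


def write_ground_truth(truth: GroundTruth, outdir: str | Path, config: dict[str, Any] | None = None) -> None:
    """Sidecar directory: theta.tsv, beta.tsv, delta.tsv + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K, V = truth.beta.shape
    comms = [f"C{j + 1}" for j in range(K)]
    taxa = [f"T{i + 1:04d}" for i in range(V)]
    samples = [f"S{d + 1:04d}" for d in range(truth.theta.shape[0])]
    _write_matrix(outdir / "theta.tsv", truth.theta, samples, comms)
    _write_matrix(outdir / "beta.tsv", truth.beta, comms, taxa)
    _write_matrix(outdir / "delta.tsv", truth.delta, comms, taxa)
    write_manifest(outdir, config or {})


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    theta = pd.read_csv(outdir / "theta.tsv", sep="\t", index_col=0).to_numpy()
    beta = pd.read_csv(outdir / "beta.tsv", sep="\t", index_col=0).to_numpy()
    delta = pd.read_csv(outdir / "delta.tsv", sep="\t", index_col=0).to_numpy().astype(np.int8)
    D, K = theta.shape
    V = beta.shape[1]
    return GroundTruth(theta=theta, beta=beta, delta=delta, z_counts=np.zeros((D, K, V), dtype=np.int64))


def write_fit(fit: Fit, outdir: str | Path, draws: PosteriorDraws | None = None) -> None:
    """Fit directory: beta.tsv, theta.tsv (and pi.tsv/delta_hat.tsv for the
    zero-inflated model) + manifest.json; optionally a retained-draws archive
    (draws.npz) for posterior predictive checks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K, V = fit.beta.shape
    comms = [f"C{j + 1}" for j in range(K)]
    taxa = list(fit.provenance.get("taxon_ids", [f"T{i + 1:04d}" for i in range(V)]))
    samples = [f"S{d + 1:04d}" for d in range(fit.theta.shape[0])]
    _write_matrix(outdir / "beta.tsv", fit.beta, comms, taxa)
    _write_matrix(outdir / "theta.tsv", fit.theta, samples, comms)
    if fit.pi_hat is not None:
        _write_matrix(outdir / "pi.tsv", fit.pi_hat, comms, taxa)
    if fit.delta_hat is not None:
        _write_matrix(outdir / "delta_hat.tsv", fit.delta_hat, comms, taxa)
    if draws is not None:
        np.savez_compressed(outdir / "draws.npz", beta=draws.beta, theta=draws.theta, delta=draws.delta)
    write_manifest(outdir, dict(fit.provenance))


def read_fit(outdir: str | Path) -> Fit:
    outdir = Path(outdir)
    beta = pd.read_csv(outdir / "beta.tsv", sep="\t", index_col=0)
    theta = pd.read_csv(outdir / "theta.tsv", sep="\t", index_col=0).to_numpy()
    pi_path = outdir / "pi.tsv"
    delta_path = outdir / "delta_hat.tsv"
    provenance: dict[str, Any] = {}
    mpath = outdir / "manifest.json"
    if mpath.exists():
        provenance = json.loads(mpath.read_text())
    provenance.setdefault("taxon_ids", list(beta.columns.astype(str)))
    return Fit(
        beta=beta.to_numpy(),
        theta=theta,
        pi_hat=pd.read_csv(pi_path, sep="\t", index_col=0).to_numpy() if pi_path.exists() else None,
        delta_hat=pd.read_csv(delta_path, sep="\t", index_col=0).to_numpy().astype(np.int8)
        if delta_path.exists()
        else None,
        provenance=provenance,
    )


def read_draws(outdir: str | Path) -> PosteriorDraws:
    data = np.load(Path(outdir) / "draws.npz")
    meta: dict[str, Any] = {}
    mpath = Path(outdir) / "manifest.json"
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    return PosteriorDraws(beta=data["beta"], theta=data["theta"], delta=data["delta"], meta=meta)
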