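"""Plain-text file I/O: histograms, trajectories, tables, run metadata.

Everything is CSV/TSV with explicit headers; no binary formats (raw
cytometry files are out of scope — inputs are pre-binned histograms).
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .rates import ValidationError


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line."""


def read_histogram(path) -> np.ndarray:
    """Read a CSV histogram (header ``bin,count``) into a frequency vector.

    Bins are molecule numbers (or intensity bin indices); missing bins
    are zero-filled up to the maximum present.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty input file")
    lines = text.splitlines()
    header = [c.strip().lower() for c in lines[0].split(",")]
    if header[:2] != ["bin", "count"]:
        raise ParseError(f"{path}:1: expected header 'bin,count', got {lines[0]!r}")
    bins, counts = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            b = int(float(parts[0]))
            c = float(parts[1])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{ln}: non-numeric cell in {line!r}") from None
        if b < 0 or c < 0:
            raise ParseError(f"{path}:{ln}: negative bin or count in {line!r}")
        bins.append(b)
        counts.append(c)
    if not bins:
        warnings.warn(f"{path}: header-only histogram, returning empty vector")
        return np.zeros(0)
    vec = np.zeros(max(bins) + 1)
    for b, c in zip(bins, counts):
        vec[b] += c
    return vec


def write_histogram(path, vector) -> None:
    vec = np.asarray(vector, dtype=float)
    if np.any(vec < 0):
        raise ValidationError("histogram counts must be >= 0")
    df = pd.DataFrame({"bin": np.arange(vec.size), "count": vec})
    df.to_csv(path, index=False)


def write_snapshots(path, states) -> None:
    """Population snapshots as CSV: n, phase, frequency, time_h."""
    rows = []
    for st in states:
        N, k = st.N, st.k
        for i in range(k):
            for n in range(N + 1):
                rows.append({"n": n, "phase": i + 1,
                             "frequency": st.F[n, i], "time_h": st.t})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labelled2d(path, dists) -> None:
    """2D labelled/total distributions as CSV: n, l, count, time_h."""
    rows = []
    for d in dists:
        tab = d.table()
        ns, ls = np.nonzero(tab)
        for n, l in zip(ns, ls):
            rows.append({"n": int(n), "l": int(l),
                         "count": tab[n, l], "time_h": d.t})
    pd.DataFrame(rows, columns=["n", "l", "count", "time_h"]).to_csv(path, index=False)


def write_trajectories(path, trajs) -> None:
    """SCT event lists as TSV: cell, time_h, event, n_before, n_after, phase."""
    rows = []
    for tr in trajs:
        for ev in tr.events:
            rows.append({"cell": tr.cell, "time_h": ev.time, "event": ev.type,
                         "n_before": ev.n_before, "n_after": ev.n_after,
                         "phase": ev.phase})
    pd.DataFrame(rows, columns=["cell", "time_h", "event", "n_before",
                                "n_after", "phase"]).to_csv(path, sep="\t", index=False)


def write_gene_trajectories(path, genes) -> None:
    """Gene time courses as TSV: gene, time_min, T, P, D."""
    rows = []
    for g in genes:
        for j, t in enumerate(g.times):
            rows.append({"gene": g.gene, "time_min": t,
                         "T": g.T[j], "P": g.P[j], "D": g.D[j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_trajectories(path):
    """Read the TSV written by :func:`write_gene_trajectories`."""
    from .trajectories import GeneTrajectory

    df = pd.read_csv(path, sep="\t")
    genes = []
    for gene, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("time_min")
        genes.append(GeneTrajectory(str(gene), grp["time_min"].to_numpy(),
                                    grp["T"].to_numpy(), grp["P"].to_numpy(),
                                    grp["D"].to_numpy()))
    return genes


def write_metadata(path, config: dict, seed=None) -> None:
    """Run metadata: config echo, seed, package/python versions."""
    from . import __version__

    meta = {
        "config": config,
        "seed": seed,
        "pwlid_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
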