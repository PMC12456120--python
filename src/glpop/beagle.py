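"""Beagle genotype-likelihood file reader/writer (gzip-transparent).

Format: tab-separated, header ``marker allele1 allele2 Ind0 Ind0 Ind0
Ind1 ...``; marker is ``scaffold_pos`` (1-based position), alleles are
coded 0=A, 1=C, 2=G, 3=T, and each individual contributes three
likelihood columns scaled so the maximum of the triple is 1.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BeagleData:
    """Sites, alleles and the (S, N, 3) scaled-likelihood tensor."""

    sites: pd.DataFrame  # columns: scaffold, pos, major, minor (codes 0-3)
    gl: np.ndarray
    samples: list[str]


def _opener(path, mode):
    if str(path).endswith(".gz"):
        # mtime=0 so identical content gives identical bytes
        return gzip.GzipFile(path, mode, mtime=0)
    return open(path, mode)


def write_beagle(path, sites: pd.DataFrame, gl: np.ndarray, samples=None) -> None:
    """Write a Beagle GL file; gzip-compressed when path ends in .gz."""
    S, N, _ = gl.shape
    if samples is None:
        samples = [f"Ind{i}" for i in range(N)]
    header = ["marker", "allele1", "allele2"]
    for s in samples:
        header += [s, s, s]
    with _opener(path, "wb") as fh:
        txt = io.TextIOWrapper(fh, encoding="ascii", newline="\n")
        txt.write("\t".join(header) + "\n")
        flat = gl.reshape(S, 3 * N)
        markers = sites["scaffold"].astype(str) + "_" + sites["pos"].astype(str)
        a1 = sites["major"].to_numpy()
        a2 = sites["minor"].to_numpy()
        for s in range(S):
            row = "\t".join(f"{v:.6g}" for v in flat[s])
            txt.write(f"{markers.iloc[s]}\t{a1[s]}\t{a2[s]}\t{row}\n")
        txt.flush()


def read_beagle(path) -> BeagleData:
    """Read a Beagle GL file written by :func:`write_beagle` (or ANGSD)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[3::3]  # one name repeated per likelihood column
    try:
        df = pd.read_csv(path, sep="\t", header=None, skiprows=1)
    except pd.errors.EmptyDataError:
        sites = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in
             [("scaffold", str), ("pos", np.int64), ("major", np.int64), ("minor", np.int64)]}
        )
        return BeagleData(sites=sites, gl=np.zeros((0, len(samples), 3)), samples=samples)
    marker = df.iloc[:, 0].astype(str)
    scaffold, pos = zip(*(m.rsplit("_", 1) for m in marker))
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": np.array(pos, dtype=np.int64),
            "major": df.iloc[:, 1].to_numpy(dtype=np.int64),
            "minor": df.iloc[:, 2].to_numpy(dtype=np.int64),
        }
    )
    gl = df.iloc[:, 3:].to_numpy(dtype=np.float64).reshape(len(df), -1, 3)
    return BeagleData(sites=sites, gl=gl, samples=samples)
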