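"""Strand-specific per-base coverage tracks and bedGraph I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoverageTrack:
    """Per-base read depth on the plus and minus strands of one replicon."""

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape:
            raise ValueError("strand tracks differ in length")

    def __len__(self) -> int:
        return len(self.plus)

    def strand(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"bad strand {strand!r}")


def write_bedgraph(depth: np.ndarray, path, chrom: str = "plasmid") -> None:
    """Write a depth vector as bedGraph (0-based half-open, zero runs skipped)."""
    depth = np.asarray(depth)
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        # run-length encode
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(depth)]])
        for s, e in zip(starts, ends):
            v = depth[s]
            if v == 0:
                continue
            sv = int(v) if float(v).is_integer() else float(v)
            fh.write(f"{chrom}\t{s}\t{e}\t{sv}\n")


def read_bedgraph(path, genome_length: int) -> np.ndarray:
    """Read a bedGraph file into a dense depth vector of `genome_length`."""
    depth = np.zeros(genome_length, dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            _, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if not 0 <= s < e <= genome_length:
                raise ValueError(f"bedGraph interval [{s},{e}) outside genome")
            depth[s:e] = float(v)
    return depth
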