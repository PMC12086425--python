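"""LD reference panel: per-block SNV correlation matrices.

Blocks are mutually independent; within a block the correlation matrix is
dense and positive semi-definite with unit diagonal.  Cross-block LD is zero
by construction, mirroring how window/block-based procedures (clumping,
LD-score regression, local covariance scans) consume a reference panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["LDPanel"]


@dataclass
class LDPanel:
    """Per-block SNV correlation matrices keyed by genomic position.

    Attributes
    ----------
    blocks : list of (m, m) correlation matrices.
    snv_ids : per-block SNV identifier arrays, concatenating to the panel's
        SNV universe in (chr, pos) order.
    chrom, pos : per-block coordinate arrays (1-based positions).
    """

    blocks: List[np.ndarray]
    snv_ids: List[np.ndarray]
    chrom: List[np.ndarray]
    pos: List[np.ndarray]
    _index: Dict[str, Tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            for b, ids in enumerate(self.snv_ids):
                for j, sid in enumerate(ids):
                    self._index[str(sid)] = (b, j)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_snvs(self) -> int:
        return sum(len(ids) for ids in self.snv_ids)

    def locate(self, snv_id: str) -> Optional[Tuple[int, int]]:
        """(block, within-block index) of a SNV, or None if uncovered."""
        return self._index.get(snv_id)

    def r2(self, snv_a: str, snv_b: str) -> Optional[float]:
        """Squared correlation between two SNVs.

        Cross-block pairs are LD-free (0.0).  Returns None when either SNV is
        not covered by the panel; callers decide the fail-open policy.
        """
        la, lb = self.locate(snv_a), self.locate(snv_b)
        if la is None or lb is None:
            return None
        if la[0] != lb[0]:
            return 0.0
        r = self.blocks[la[0]][la[1], lb[1]]
        return float(r * r)

    def block_of(self, snv_id: str) -> Optional[int]:
        loc = self.locate(snv_id)
        return None if loc is None else loc[0]

    def validate(self) -> None:
        """Assert unit diagonals and positive semi-definiteness."""
        for b, R in enumerate(self.blocks):
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise AssertionError(f"block {b}: diagonal not unit")
            w = np.linalg.eigvalsh(R)
            if w.min() < -1e-8:
                raise AssertionError(
                    f"block {b}: not PSD (min eigenvalue {w.min():.3e})"
                )

    # ---- I/O: one matrix file per block plus a JSON index -----------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for b, R in enumerate(self.blocks):
            fname = f"block_{b:04d}.tsv"
            np.savetxt(directory / fname, R, delimiter="\t", fmt="%.10g")
            index.append(
                {
                    "file": fname,
                    "snv_ids": [str(s) for s in self.snv_ids[b]],
                    "chrom": [int(c) for c in self.chrom[b]],
                    "pos": [int(p) for p in self.pos[b]],
                }
            )
        (directory / "index.json").write_text(json.dumps(index))

    @classmethod
    def read(cls, directory: str | Path) -> "LDPanel":
        directory = Path(directory)
        index = json.loads((directory / "index.json").read_text())
        blocks, ids, chrom, pos = [], [], [], []
        for entry in index:
            R = np.loadtxt(directory / entry["file"], delimiter="\t", ndmin=2)
            blocks.append(R)
            ids.append(np.array(entry["snv_ids"], dtype=object))
            chrom.append(np.array(entry["chrom"], dtype=int))
            pos.append(np.array(entry["pos"], dtype=int))
        return cls(blocks=blocks, snv_ids=ids, chrom=chrom, pos=pos)
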