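"""File formats: FASTA, Newick, TSV truth/hit tables, and run configuration.

All column coordinates written to disk are 0-based half-open; file headers
say so.  FASTA parsing is strict: duplicate ids are rejected, lowercase
residues are normalized to uppercase, and malformed input raises an error
with the offending line number.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "RunConfig",
]

logger = logging.getLogger("markerdiv")

_VALID_CHARS = set("ABCDEFGHIKLMNPQRSTUVWXYZ*-")


class FastaParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    records[current] = "".join(chunks)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                name = header.split()[0]
                if name in records or name == current:
                    raise FastaParseError(f"duplicate id {name!r}", lineno)
                current = name
                chunks = []
            else:
                if current is None:
                    raise FastaParseError("sequence data before first header", lineno)
                seq = line.strip()
                if seq != seq.upper():
                    logger.info("normalized lowercase residues at line %d", lineno)
                    seq = seq.upper()
                bad = set(seq) - _VALID_CHARS
                if bad:
                    raise FastaParseError(
                        f"illegal residue {sorted(bad)[0]!r}", lineno
                    )
                chunks.append(seq)
    if current is not None:
        records[current] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree (branch lengths default to 0)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node.parent_node is not None:
            edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                preserve_spaces=True,
                suppress_rooting=True,
                real_value_format_specifier=".6g",
            )
        )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; round-trips losslessly via YAML."""

    # synthetic community design
    groups: list[list] = field(default_factory=lambda: [
        ["V", 18, 1.6, 0.05], ["B", 6, 0.8, 0.05], ["A", 6, 0.8, 0.05],
    ])
    fragment_count: int = 600
    fragment_min_len: int = 150
    fragment_max_len: int | None = None
    alignment_len: int = 300
    stem_depth: float = 1.0
    # screening
    evalue_max: float = 1e-5
    min_len: int = 150
    n_null: int = 300
    match_gap_frac: float = 0.5
    # windows / richness
    window_width: int = 100
    window_step: int = 10
    max_gap_frac: float = 0.10
    cutoffs: list[float] = field(default_factory=lambda: [0.70, 0.80, 0.90])
    resample_n: int = 100
    n_replicates: int = 10
    pd_subsample: int = 100
    # optional selection stage: list of [group, omega, n_pairs]
    codon_groups: list[list] = field(default_factory=list)
    codon_n: int = 500
    codon_t: float = 0.4
    codon_kappa: float = 2.0
    # seeds
    seed: int = 0

    def __post_init__(self):
        for name in ("evalue_max", "window_width", "window_step", "resample_n",
                     "n_replicates", "pd_subsample", "min_len", "n_null"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
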