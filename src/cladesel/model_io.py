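"""Readers and writers for the formats the tool touches.

Neutral models come as phyloFit-style ``.mod`` files (SUBST_MOD, BACKGROUND,
RATE_MAT and TREE records).  Alignments are MAF or aligned FASTA; predictions
go out as BED6 plus a TSV audit dump.  Coordinates are 0-based half-open
everywhere, including BED output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import MISSING, decode, encode
from .phylo import PhyloModel, PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "ModelFormatError",
    "NeutralModelFile",
    "AlignmentBlock",
    "read_mod",
    "write_mod",
    "load_default_model",
    "read_maf",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "write_bed",
    "read_config",
]


class ModelFormatError(ValueError):
    """Raised for malformed .mod / alignment inputs."""


@dataclass
class NeutralModelFile:
    """Parsed phyloFit-style neutral model: substitution model name,
    equilibrium base frequencies (A,C,G,T), 4x4 rate matrix and the Newick
    tree with branch lengths in expected substitutions per site."""

    subst_mod: str
    background: np.ndarray
    rate_matrix: np.ndarray
    tree_newick: str

    def to_phylo_model(self) -> PhyloModel:
        tree = PhyloTree.from_newick(self.tree_newick)
        return PhyloModel(tree, self.rate_matrix, self.background)


def read_mod(path: str | Path) -> NeutralModelFile:
    """Parse a phyloFit-style .mod file and validate its records."""
    path = Path(path)
    records: dict[str, list[str]] = {}
    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line and line.split(":", 1)[0].isupper():
            key, rest = line.split(":", 1)
            current = key.strip()
            records[current] = [rest.strip()] if rest.strip() else []
        elif current is not None:
            records[current].append(line)
    for req in ("BACKGROUND", "RATE_MAT", "TREE"):
        if req not in records:
            raise ModelFormatError(f"{path}: missing required record {req}")
    background = np.array([float(x) for x in " ".join(records["BACKGROUND"]).split()])
    if background.shape != (4,):
        raise ModelFormatError(f"{path}: BACKGROUND must have 4 frequencies")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ModelFormatError(
            f"{path}: BACKGROUND sums to {background.sum():.6f}, expected 1"
        )
    rows = [[float(x) for x in r.split()] for r in records["RATE_MAT"] if r.split()]
    rate = np.array(rows, dtype=np.float64)
    if rate.shape != (4, 4):
        raise ModelFormatError(f"{path}: RATE_MAT must be 4x4, got {rate.shape}")
    flux = background[:, None] * rate
    if np.max(np.abs(flux - flux.T)) > 1e-4 * np.max(np.abs(rate)):
        log.warning("%s: rate matrix violates detailed balance (not time-reversible)", path)
    tree_newick = " ".join(records["TREE"]).strip()
    if not tree_newick.endswith(";"):
        tree_newick += ";"
    mod = NeutralModelFile(
        subst_mod=" ".join(records.get("SUBST_MOD", ["REV"])) or "REV",
        background=background,
        rate_matrix=rate,
        tree_newick=tree_newick,
    )
    # fails fast if the tree does not parse
    mod.to_phylo_model()
    return mod


def write_mod(mod: NeutralModelFile, path: str | Path) -> None:
    path = Path(path)
    tree = PhyloTree.from_newick(mod.tree_newick)
    with path.open("w") as fh:
        fh.write(f"SUBST_MOD: {mod.subst_mod}\n")
        fh.write("BACKGROUND: " + " ".join(f"{x:.12g}" for x in mod.background) + "\n")
        fh.write("RATE_MAT:\n")
        for row in mod.rate_matrix:
            fh.write("  " + " ".join(f"{x: .12g}" for x in row) + "\n")
        fh.write(f"TREE: {tree.to_newick()}\n")


def load_default_model() -> NeutralModelFile:
    """The packaged 14-taxon primate-like neutral model (synthetic stand-in
    estimated to resemble fourfold-degenerate-site models of primates)."""
    ref = resources.files("cladesel.data").joinpath("primate14.mod")
    with resources.as_file(ref) as p:
        return read_mod(p)


@dataclass
class AlignmentBlock:
    """Column-indexed multiple alignment over {A,C,G,T,missing}.

    ``codes`` is (n_species, L) uint8.  ``ref_name``/``ref_start``/``strand``
    map columns of the reference row (row 0 by default) to genome positions.
    """

    species: list[str]
    codes: np.ndarray
    ref_name: str = "ref"
    ref_start: int = 0
    strand: str = "+"
    ref_row: int = 0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.species):
            raise ModelFormatError("codes must be (n_species, L) matching species list")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_strings(cls, rows: dict[str, str], **kw) -> "AlignmentBlock":
        species = list(rows)
        lens = {len(s) for s in rows.values()}
        if len(lens) > 1:
            raise ModelFormatError(f"rows have unequal lengths {sorted(lens)}")
        codes = np.vstack([encode(rows[sp]) for sp in species]) if species else np.zeros((0, 0), np.uint8)
        return cls(species, codes, **kw)

    def row_str(self, sp: str) -> str:
        return decode(self.codes[self.species.index(sp)])

    def codes_for_tree(self, tree: PhyloTree) -> np.ndarray:
        """Rows reordered to tree leaf order; species absent from the block
        become all-missing rows, block species absent from the tree are
        dropped with a warning."""
        leaf_labels = tree.leaf_labels
        extra = [sp for sp in self.species if sp not in leaf_labels]
        if extra:
            log.warning("dropping alignment rows with no tree leaf: %s", ",".join(extra))
        out = np.full((len(leaf_labels), self.L), MISSING, dtype=np.uint8)
        for i, lab in enumerate(leaf_labels):
            if lab in self.species:
                out[i] = self.codes[self.species.index(lab)]
        return out

    def genome_coordinates(self) -> np.ndarray:
        """(L+1,) genomic offsets of column boundaries on the reference row.

        ``coord[i]`` is the genome position of the left edge of column i;
        reference-gap columns advance nothing, so the mapping is monotone
        non-decreasing and column interval [a, b) maps to genomic
        [coord[a], coord[b])."""
        ref = self.codes[self.ref_row]
        steps = (ref != MISSING).astype(np.int64)
        return self.ref_start + np.concatenate([[0], np.cumsum(steps)])


def read_maf(path: str | Path, species_filter: set[str]) -> list[AlignmentBlock]:
    """Read MAF blocks restricted to ``species_filter``.

    Species absent from a block are filled with missing-data rows of the
    block's length.  The first requested species present in a block is the
    reference row for coordinate mapping.
    """
    if not species_filter:
        raise ValueError("species_filter must be non-empty")
    blocks: list[AlignmentBlock] = []
    try:
        msas = list(AlignIO.parse(str(path), "maf"))
    except ValueError as e:
        raise ModelFormatError(f"{path}: malformed MAF: {e}") from e
    for msa in msas:
        present: dict[str, object] = {}
        for rec in msa:
            sp = rec.id.split(".", 1)[0]
            if sp in species_filter and sp not in present:
                present[sp] = rec
        if not present:
            continue
        L = msa.get_alignment_length()
        # MAF convention: the block's first requested row is the reference
        order = list(present) + sorted(species_filter - present.keys())
        codes = np.full((len(order), L), MISSING, dtype=np.uint8)
        for i, sp in enumerate(order):
            if sp in present:
                codes[i] = encode(str(present[sp].seq))
        ref = present[order[0]]
        ann = getattr(ref, "annotations", {})
        blocks.append(
            AlignmentBlock(
                order,
                codes,
                ref_name=ref.id,
                ref_start=int(ann.get("start", 0)),
                strand="-" if ann.get("strand", 1) in (-1, "-") else "+",
            )
        )
    return blocks


def read_fasta_alignment(
    path: str | Path, species_filter: set[str] | None = None
) -> AlignmentBlock:
    """Read a pre-extracted aligned FASTA block (one row per species)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = rec.id.split(".", 1)[0]
        if species_filter is None or sp in species_filter:
            rows[sp] = str(rec.seq)
    if not rows:
        raise ModelFormatError(f"{path}: no usable FASTA records")
    return AlignmentBlock.from_strings(rows)


def write_fasta_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, sp in enumerate(block.species):
            fh.write(f">{sp}\n")
            row = decode(block.codes[i])
            for j in range(0, len(row), 80):
                fh.write(row[j : j + 80] + "\n")


def write_bed(elements, block: AlignmentBlock, path: str | Path) -> None:
    """Write primary predicted elements as BED6.

    Alignment columns are mapped through the reference row (gaps skipped);
    the name field encodes ``type|node|rho`` and the score column is the
    interval log-ratio score clipped into [0, 1000] after scaling by 10.
    """
    coord = block.genome_coordinates()
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for el in elements:
            if getattr(el, "suppressed_by_overlap", False):
                continue
            if el.end > block.L:
                raise ValueError(
                    f"element [{el.start},{el.end}) extends past block of length {block.L}"
                )
            name = f"{el.scenario.stype}|{el.scenario.node_label or 'all'}|{el.rho:g}"
            score = int(np.clip(round(10.0 * el.score), 0, 1000))
            fh.write(
                f"{block.ref_name}\t{coord[el.start]}\t{coord[el.end]}\t"
                f"{name}\t{score}\t{block.strand}\n"
            )


def read_config(path: str | Path) -> dict[str, str]:
    """Plain-text key=value run configuration (lines starting with # ignored)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ModelFormatError(f"{path}: bad config line {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
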