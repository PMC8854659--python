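"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: everything is 0-based half-open internally; GFF3
(1-based inclusive) is converted at the boundary only.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .phylo import NeutralModel, PhyloTree, SubstitutionModel, parse_newick

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "element_id", "chrom", "start", "end", "branch_label",
    "lnl_null", "lnl_alt", "s_hat", "rho_hat", "lrt", "p_emp", "q_fdr",
]


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


# ---------------------------------------------------------------------------
# Genomic intervals and gene models
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Gene identifier with its coding span (first to last coding base)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None


# ---------------------------------------------------------------------------
# phast .mod dialect
# ---------------------------------------------------------------------------

def read_mod(path: str | Path | IO[str]) -> NeutralModel:
    """Read a neutral model in the phast ``.mod`` dialect.

    Requires ``BACKGROUND``, ``RATE_MAT`` and ``TREE`` keys and a REV-family
    ``SUBST_MOD``.  Frequencies within 1e-6 of summing to 1 are accepted and
    renormalized; the rate matrix is symmetrized onto the REV manifold and
    rescaled to 1 expected substitution per site.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    fields: dict[str, str] = {}
    rate_rows: list[list[float]] = []
    in_rate = False
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if in_rate and not stripped[0].isalpha():
            rate_rows.append([float(x) for x in stripped.split()])
            continue
        in_rate = False
        if ":" not in stripped:
            raise FormatError(f"unparseable .mod line: {line!r}")
        key, _, value = stripped.partition(":")
        key = key.strip().upper()
        if key == "RATE_MAT":
            in_rate = True
            if value.strip():
                rate_rows.append([float(x) for x in value.split()])
        else:
            fields[key] = value.strip()

    subst_mod = fields.get("SUBST_MOD", "REV").upper()
    if subst_mod not in {"REV", "JC69"}:
        raise FormatError(f"unsupported SUBST_MOD {subst_mod!r}; only the "
                          "reversible family (REV, JC69) is handled")
    for required in ("TREE", "BACKGROUND"):
        if required not in fields:
            raise FormatError(f"missing required .mod key {required!r}")
    if not rate_rows:
        raise FormatError("missing required .mod key 'RATE_MAT'")
    if len(rate_rows) != 4 or any(len(r) != 4 for r in rate_rows):
        raise FormatError("RATE_MAT must be 4 rows of 4 reals")

    pi = np.array([float(x) for x in fields["BACKGROUND"].split()])
    if pi.shape != (4,):
        raise FormatError("BACKGROUND must hold 4 reals")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise FormatError(f"BACKGROUND sums to {pi.sum():.8f}")
    pi = pi / pi.sum()

    q = np.array(rate_rows, dtype=float)
    # project onto the REV manifold: average the exchangeabilities implied
    # by Q_ij = r_ij * pi_j both ways, then rebuild and renormalize
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(pi[None, :] > 0, q / pi[None, :], 0.0)
    r = (r + r.T) / 2.0
    iu = np.triu_indices(4, k=1)
    subst = SubstitutionModel.general_reversible(pi, r[iu])

    tree = parse_newick(fields["TREE"])
    model = NeutralModel(tree, subst)
    model.validate()
    return model


def write_mod(model: NeutralModel, path: str | Path) -> None:
    pi = model.subst.freqs
    q = model.subst.rate_matrix
    with open(path, "w") as fh:
        fh.write("ALPHABET: A C G T\n")
        fh.write("ORDER: 0\n")
        fh.write("SUBST_MOD: REV\n")
        fh.write("BACKGROUND: " + " ".join(f"{x:.17g}" for x in pi) + "\n")
        fh.write("RATE_MAT:\n")
        for row in q:
            fh.write("  " + " ".join(f"{x:.17g}" for x in row) + "\n")
        fh.write("TREE: " + model.tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MafRow:
    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]


@dataclasses.dataclass(frozen=True)
class MafBlock:
    rows: tuple[MafRow, ...]

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


def read_maf(path: str | Path | IO[str]) -> Iterator[MafBlock]:
    """Stream alignment blocks from a MAF file, validating row geometry.

    Yields blocks in file order; only one block is held in memory at a time.
    """
    fh = open(path) if not hasattr(path, "read") else path
    own = fh is not path
    block_index = 0
    rows: list[MafRow] = []

    def finish() -> MafBlock | None:
        nonlocal block_index, rows
        if not rows:
            return None
        widths = {len(r.text) for r in rows}
        if len(widths) > 1:
            raise FormatError(
                f"block {block_index}: aligned texts differ in length")
        for r in rows:
            ungapped = sum(1 for c in r.text if c != "-")
            if ungapped != r.size:
                raise FormatError(
                    f"block {block_index}: row {r.src!r} declares size "
                    f"{r.size} but has {ungapped} aligned bases")
        block = MafBlock(tuple(rows))
        rows = []
        block_index += 1
        return block

    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "a":
                block = finish()
                if block is not None:
                    yield block
            elif parts[0] == "s":
                if len(parts) != 7:
                    raise FormatError(
                        f"block {block_index}: malformed 's' line: {line!r}")
                rows.append(MafRow(parts[1], int(parts[2]), int(parts[3]),
                                   parts[4], int(parts[5]), parts[6]))
            # other line types (i/e/q) are ignored
        block = finish()
        if block is not None:
            yield block
    finally:
        if own:
            fh.close()


def write_maf(blocks: Iterable[MafBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in blocks:
            fh.write("a score=0.0\n")
            width = max((len(r.src) for r in block.rows), default=0)
            for r in block.rows:
                fh.write(f"s {r.src:<{width}} {r.start} {r.size} "
                         f"{r.strand} {r.src_size} {r.text}\n")
            fh.write("\n")


@dataclasses.dataclass
class ExtractedAlignment:
    """Reference-projected sub-alignment for one interval."""

    seqs: dict[str, str]
    covered: int          # reference positions covered by >= 1 block

    @property
    def has_data(self) -> bool:
        return self.covered > 0


def extract_interval_alignment(
    blocks: Sequence[MafBlock],
    interval: GenomicInterval,
    species: Sequence[str],
    ref_species: str,
) -> ExtractedAlignment:
    """Pull the per-species alignment for one reference interval.

    Columns where the reference has a gap are dropped, so the result has
    exactly ``interval.width`` columns in reference coordinates; positions
    not covered by any block, and species absent from covering blocks, are
    filled with ``-`` (missing).  Zero-coverage intervals come back flagged
    rather than raising.
    """
    width = interval.width
    cols = {sp: ["-"] * width for sp in species}
    covered = np.zeros(width, dtype=bool)
    for block in blocks:
        ref = block.row_for(ref_species)
        if ref is None or ref.chrom != interval.chrom or ref.strand != "+":
            continue
        ref_end = ref.start + ref.size
        if ref_end <= interval.start or ref.start >= interval.end:
            continue
        others = [r for r in block.rows
                  if r.species != ref_species and r.species in cols]
        pos = ref.start
        for c, ref_char in enumerate(ref.text):
            if ref_char == "-":
                continue
            if interval.start <= pos < interval.end:
                off = pos - interval.start
                covered[off] = True
                cols[ref_species][off] = ref_char
                for row in others:
                    cols[row.species][off] = row.text[c]
            pos += 1
            if pos >= interval.end:
                break
    seqs = {sp: "".join(chars) for sp, chars in cols.items()}
    return ExtractedAlignment(seqs, int(covered.sum()))


# ---------------------------------------------------------------------------
# BED / gene models / gene lists
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"BED line with fewer than 3 columns: {raw!r}")
        name = parts[3] if len(parts) > 3 else None
        strand = parts[5] if len(parts) > 5 else None
        out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                   name, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              scores: Sequence[float] | None = None) -> None:
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if scores is not None:
                cols.append(str(int(round(scores[i]))))
            fh.write("\t".join(cols) + "\n")


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12; thickStart/thickEnd give the coding span."""
    genes = []
    seen = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise FormatError(f"BED12 line with fewer than 8 columns: {raw!r}")
        gene_id = parts[3]
        if gene_id in seen:
            raise FormatError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        thick_start, thick_end = int(parts[6]), int(parts[7])
        if thick_start >= thick_end:
            log.warning("gene %s has an empty coding span; skipped", gene_id)
            continue
        genes.append(GeneModel(gene_id, parts[0], thick_start, thick_end,
                               parts[5] if len(parts) > 5 else None))
    return genes


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, _, v = item.partition("=")
            out[k] = v
    return out


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3: CDS features aggregated per gene.

    The coding span runs from the first to the last coding base (introns
    included); 1-based inclusive GFF3 coordinates become 0-based half-open.
    Genes with no CDS are skipped with a logged warning.
    """
    features: dict[str, tuple[str, str | None, str]] = {}  # id -> (type, parent, name)
    cds: list[tuple[str, int, int, str | None, str | None]] = []
    gene_ids_seen: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise FormatError(f"GFF3 line with {len(parts)} columns: {raw!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = parts
        a = _gff3_attributes(attrs)
        fid = a.get("ID")
        if fid:
            features[fid] = (ftype, a.get("Parent"),
                             a.get("Name") or a.get("gene_name") or fid)
        if ftype.lower() == "gene" and fid:
            gene_ids_seen.add(fid)
        if ftype == "CDS":
            cds.append((chrom, int(start) - 1, int(end),
                        a.get("Parent"), strand))

    def resolve_gene(parent: str | None) -> str | None:
        seen = set()
        while parent is not None and parent not in seen:
            seen.add(parent)
            ftype, grand, name = features.get(parent, ("", None, parent))
            if ftype.lower() == "gene":
                return name
            if grand is None:
                return name  # orphan transcript: use its own id
            parent = grand
        return parent

    spans: dict[str, list] = {}
    resolved_genes: set[str] = set()
    for chrom, start, end, parent, strand in cds:
        gene = resolve_gene(parent) or "unknown"
        resolved_genes.add(parent or "")
        rec = spans.setdefault(gene, [chrom, start, end, strand])
        rec[1] = min(rec[1], start)
        rec[2] = max(rec[2], end)
    for gid in gene_ids_seen:
        name = features[gid][2]
        if name not in spans:
            log.warning("gene %s has no CDS features; skipped", name)
    return [GeneModel(gid, chrom, start, end, strand)
            for gid, (chrom, start, end, strand) in sorted(spans.items())]


def read_genes(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: ``.gff``/``.gff3`` vs BED12."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return read_genes_gff3(path)
    return read_genes_bed12(path)


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        name = line.strip()
        if name and not name.startswith("#"):
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table lacks columns {missing}")
    results.loc[:, RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results table lacks columns {missing}")
    return df
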