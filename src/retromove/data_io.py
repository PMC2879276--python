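"""Readers and writers for the package's external formats.

Location and expression matrices use a small documented TSV dialect (UTF-8,
tab-separated, ``#`` comment lines); trees are newick (read through
dendropy); gene models are GFF3 (read through gffutils) with a companion
ortholog-family TSV.  Packaged fixtures for the 21-gene study cohort, the
12-species tree, the Muller linkage map and the calibrated null-model
configuration are exposed through the ``load_*`` helpers.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import gffutils
import yaml

from .types import (
    AUTOSOMAL,
    MULLER_ELEMENTS,
    X_LINKED,
    ExpressionMatrix,
    GeneModel,
    LocationCell,
    LocationMatrix,
    MullerMap,
    OrthologCohort,
    OrthologSet,
    ParseError,
)

_DATA = resources.files("retromove.data")

_STATE_TOKEN = re.compile(r"^[A-FX](/[A-FX])*$")
_SECONDARY = re.compile(r"\s*\(([A-FX](?:/[A-FX])*)\)")


# ---------------------------------------------------------------------------
# location matrix


def parse_location_cell(token: str) -> LocationCell:
    """Parse one location-matrix cell token into a :class:`LocationCell`.

    Recognised markup: ``-`` missing; ``***E***`` retro copy; ``^†^``
    degraded; ``C/B`` ambiguity set; ``A (C)`` secondary retrocopy; ``^‡^``
    footnote.  Markup may combine (e.g. ``***A^†^***``).  Unknown markup
    raises :class:`ParseError`.
    """
    raw = token.strip()
    if raw == "-" or raw == "":
        return LocationCell()
    work = raw
    footnote = "^‡^" in work
    work = work.replace("^‡^", "")
    m = _SECONDARY.search(work)
    secondary: tuple[str, ...] = ()
    if m:
        secondary = tuple(m.group(1).split("/"))
        work = _SECONDARY.sub("", work)
    degraded = "^†^" in work or "†" in work
    work = work.replace("^†^", "").replace("†", "")
    retro = False
    if work.startswith("**"):
        stripped = work.strip("*")
        # require balanced 2-3 asterisk wrapping
        if not re.fullmatch(r"\*{2,3}" + re.escape(stripped) + r"\*{2,3}", work):
            raise ParseError(f"unbalanced markup in cell {token!r}")
        retro = True
        work = stripped
    work = work.strip()
    if not _STATE_TOKEN.fullmatch(work):
        raise ParseError(f"unparsable location cell {token!r}")
    return LocationCell(
        states=tuple(work.split("/")),
        retro=retro,
        degraded=degraded,
        secondary=secondary,
        footnote=footnote,
    )


def format_location_cell(cell: LocationCell) -> str:
    """Serialize a cell back to the canonical dialect token."""
    if cell.missing:
        return "-"
    body = "/".join(cell.states)
    if cell.degraded:
        body += "^†^"
    if cell.retro:
        body = f"***{body}***"
    if cell.secondary:
        body += " (" + "/".join(cell.secondary) + ")"
    if cell.footnote:
        body += "^‡^"
    return body


def _read_tsv_rows(path: Path | str) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def read_location_matrix(
    path: Path | str, species: Optional[Iterable[str]] = None
) -> LocationMatrix:
    """Read a gene x species Muller-element location matrix.

    ``species``, when given, is the declared species list: header columns
    outside it are an error.
    """
    rows = _read_tsv_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [c.strip() for c in rows[0][1:]]
    if species is not None:
        extra = set(header) - set(species)
        if extra:
            raise ParseError(f"{path}: unknown species {sorted(extra)}")
    cells: dict[str, dict[str, LocationCell]] = {}
    for row in rows[1:]:
        gene = row[0].strip()
        if gene in cells:
            raise ParseError(f"{path}: duplicate gene ID {gene}")
        if len(row) - 1 != len(header):
            raise ParseError(f"{path}: row {gene} has {len(row)-1} cells, "
                             f"expected {len(header)}")
        cells[gene] = {
            sp: parse_location_cell(tok) for sp, tok in zip(header, row[1:])
        }
    matrix = LocationMatrix(species=tuple(header), cells=cells)
    matrix.validate()
    return matrix


def write_location_matrix(matrix: LocationMatrix, path: Path | str) -> None:
    lines = ["gene\t" + "\t".join(matrix.species)]
    for gene in matrix.genes:
        row = matrix.row(gene)
        lines.append(
            gene + "\t" + "\t".join(format_location_cell(row[sp]) for sp in matrix.species)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# expression matrix


def parse_expression_cell(token: str) -> tuple[Optional[float], bool, bool]:
    """Parse one expression cell into (value, significant, retro_copy_bold)."""
    raw = token.strip()
    if raw == "-" or raw == "":
        return None, False, False
    bold = False
    work = raw
    if work.startswith("**"):
        bold = True
        work = work[2:]
        if work.endswith("***"):
            sig = True
            work = work[:-3]
        elif work.endswith("**"):
            sig = False
            work = work[:-2]
        else:
            raise ParseError(f"unbalanced bold markup in cell {token!r}")
    else:
        sig = work.endswith("*")
        if sig:
            work = work[:-1]
    try:
        value = float(work)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression cell {token!r}") from exc
    return value, sig, bold


def format_expression_cell(
    value: Optional[float], significant: bool, bold: bool
) -> str:
    if value is None:
        return "-"
    body = f"{value:.3f}"
    if bold:
        return f"**{body}**" + ("*" if significant else "")
    return body + ("*" if significant else "")


def read_expression_matrix(path: Path | str) -> ExpressionMatrix:
    rows = _read_tsv_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [c.strip() for c in rows[0][1:]]
    values: dict[str, dict[str, Optional[float]]] = {}
    sig: dict[str, dict[str, bool]] = {}
    bold: dict[str, dict[str, bool]] = {}
    for row in rows[1:]:
        gene = row[0].strip()
        if gene in values:
            raise ParseError(f"{path}: duplicate gene ID {gene}")
        values[gene], sig[gene], bold[gene] = {}, {}, {}
        for sp, tok in zip(header, row[1:]):
            v, s, b = parse_expression_cell(tok)
            values[gene][sp], sig[gene][sp], bold[gene][sp] = v, s, b
    matrix = ExpressionMatrix(
        species=tuple(header), values=values, significant=sig, retro_copy=bold
    )
    matrix.validate()
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: Path | str) -> None:
    lines = ["gene\t" + "\t".join(matrix.species)]
    for gene in matrix.genes:
        toks = [
            format_expression_cell(
                matrix.values[gene][sp],
                matrix.significant[gene][sp],
                matrix.retro_copy[gene][sp],
            )
            for sp in matrix.species
        ]
        lines.append(gene + "\t" + "\t".join(toks))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# species tree


def read_species_tree(source: Path | str | None = None,
                      data: str | None = None) -> dendropy.Tree:
    """Read a rooted newick species tree; rejects duplicate leaves and
    explicitly-unrooted (``[&U]``) input."""
    if data is None:
        data = Path(source).read_text(encoding="utf-8")
    if "[&U]" in data.upper().replace(" ", ""):
        raise ParseError("unrooted tree rejected: a rooted tree is required")
    try:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 rooting="default-rooted",
                                 suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ParseError(f"duplicate leaf labels: {exc}") from exc
    labels = [leaf.taxon.label.replace(" ", "_")
              for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels {dup}")
    return tree


def tree_leaf_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(
        leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()
    )


# ---------------------------------------------------------------------------
# Muller map


def read_muller_map(path: Path | str, species: Iterable[str]) -> MullerMap:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return muller_map_from_dict(doc, species)


def muller_map_from_dict(doc: Mapping, species: Iterable[str]) -> MullerMap:
    default = dict(doc.get("default", {}))
    overrides = doc.get("overrides", {}) or {}
    linkage = {}
    for sp in species:
        per = dict(default)
        per.update(overrides.get(sp, {}))
        for e, lk in per.items():
            if lk not in (X_LINKED, AUTOSOMAL):
                raise ParseError(f"bad linkage class {lk!r} for ({sp}, {e})")
        linkage[sp] = per
    mm = MullerMap(linkage=linkage)
    mm.validate(species)
    return mm


# ---------------------------------------------------------------------------
# gene models (GFF3 + ortholog TSV)


def _transcript_intron_counts(exons, cdss):
    """CDS-intron and UTR-only-intron counts for one transcript."""
    exons = sorted(exons)
    introns = [
        (exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)
    ]
    if not cdss:
        return len(introns), 0  # non-coding: count all introns as CDS-like
    cds_lo = min(s for s, _ in cdss)
    cds_hi = max(e for _, e in cdss)
    cds_introns = sum(1 for s, e in introns if s > cds_lo and e < cds_hi)
    utr_introns = sum(1 for s, e in introns if e < cds_lo or s > cds_hi)
    return cds_introns, utr_introns


def read_gene_models_one_species(
    gff_path: Path | str, species: str, flank_window: int = 2
) -> dict[str, GeneModel]:
    """Parse one species' GFF3 into per-gene models (min-CDS-intron isoform),
    with flanking genes resolved by coordinate order on each scaffold."""
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: dict[str, tuple[str, str, int, int, int, int]] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ParseError(f"{species}: gene {gene.id} has no mRNA")
        best = None
        for mrna in mrnas:
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cdss = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not exons:
                exons = sorted(cdss)
            counts = _transcript_intron_counts(exons, cdss)
            if best is None or counts < best:
                best = counts
        raw[gene.id] = (
            gene.seqid, gene.strand, gene.start, gene.end, best[0], best[1]
        )
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            raise ParseError(f"{species}: CDS {cds.id} without parent mRNA")
    # flanking genes by coordinate order within scaffold
    by_scaffold: dict[str, list[str]] = {}
    for gid, (scaf, _, start, _, _, _) in raw.items():
        by_scaffold.setdefault(scaf, []).append(gid)
    for scaf, gids in by_scaffold.items():
        gids.sort(key=lambda g: raw[g][2])
    models = {}
    for gid, (scaf, strand, start, end, n_cds, n_utr) in raw.items():
        order = by_scaffold[scaf]
        i = order.index(gid)
        left = tuple(reversed(order[max(0, i - flank_window):i]))
        right = tuple(order[i + 1:i + 1 + flank_window])
        models[gid] = GeneModel(
            species=species, gene_id=gid, scaffold=scaf, strand=strand,
            start=start, end=end, cds_introns=n_cds, utr_introns=n_utr,
            flank_left=left, flank_right=right,
        )
    return models


def read_gene_models(
    gff_paths: Mapping[str, Path | str],
    orthologs_path: Path | str,
    flank_window: int = 2,
) -> OrthologCohort:
    """Ingest per-species GFF3 files plus an ortholog-family TSV
    (columns: family, species, gene) into an :class:`OrthologCohort`."""
    per_species = {
        sp: read_gene_models_one_species(p, sp, flank_window)
        for sp, p in gff_paths.items()
    }
    families: dict[str, OrthologSet] = {}
    gene_to_family: dict[str, str] = {}
    for row in _read_tsv_rows(orthologs_path):
        if row[0].strip().lower() == "family":
            continue
        fam, sp, gid = (c.strip() for c in row[:3])
        if sp not in per_species or gid not in per_species[sp]:
            raise ParseError(f"ortholog row references absent gene {gid} ({sp})")
        families.setdefault(fam, OrthologSet(family_id=fam))
        families[fam].members.setdefault(sp, []).append(per_species[sp][gid])
        gene_to_family[gid] = fam
    return OrthologCohort(
        families=[families[f] for f in sorted(families)],
        gene_to_family=gene_to_family,
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture(name: str) -> Path:
    return Path(str(_DATA / name))


def load_table1() -> LocationMatrix:
    """The packaged 21-gene x 12-species Muller-element location matrix."""
    return read_location_matrix(_fixture("table1_locations.tsv"))


def load_table2() -> ExpressionMatrix:
    """The packaged 21-gene x 6-species sex-bias expression matrix."""
    return read_expression_matrix(_fixture("table2_expression.tsv"))


def load_default_tree() -> dendropy.Tree:
    """The accepted rooted 12-species Drosophila topology."""
    return read_species_tree(_fixture("drosophila_12sp.nwk"))


def load_default_muller_map() -> MullerMap:
    """Muller element -> linkage per species, with the obscura neo-X."""
    from .types import SPECIES_12

    return read_muller_map(_fixture("muller_map.yaml"), SPECIES_12)


def default_null_config_path() -> Path:
    return _fixture("null_dmel.yaml")
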