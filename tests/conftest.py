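import pytest

from retromove import data_io
from retromove.null_model_stats import load_default_null_config
from retromove.types import GeneModel, LocationMatrix, OrthologCohort, OrthologSet


@pytest.fixture(scope="session")
def table1():
    return data_io.load_table1()


@pytest.fixture(scope="session")
def table2():
    return data_io.load_table2()


@pytest.fixture(scope="session")
def tree():
    return data_io.load_default_tree()


@pytest.fixture(scope="session")
def muller():
    return data_io.load_default_muller_map()


@pytest.fixture(scope="session")
def null_cfg():
    return load_default_null_config()


def make_model(species, gene_id, cds_introns, scaffold="scaf1", start=1,
               utr_introns=0, flank_left=(), flank_right=(), degraded=False,
               strand="+"):
    return GeneModel(
        species=species, gene_id=gene_id, scaffold=scaffold, strand=strand,
        start=start, end=start + 899, cds_introns=cds_introns,
        utr_introns=utr_introns, flank_left=tuple(flank_left),
        flank_right=tuple(flank_right), degraded=degraded,
    )


def cohort_from_locations(matrix: LocationMatrix,
                          utr_only=("CG4918",)) -> OrthologCohort:
    """Reconstruct an ortholog cohort mirroring a location matrix: one copy
    per non-missing, non-degraded cell; retro cells intronless in a fresh
    flanking context, parental cells intron-bearing in the ancestral
    context.  Genes in ``utr_only`` get UTR-only introns on their
    intronless copies."""
    families = []
    g2f = {}
    for gene in matrix.genes:
        fam = OrthologSet(family_id=gene)
        for sp in matrix.species:
            cell = matrix.cell(gene, sp)
            if cell.missing or cell.degraded:
                continue
            gid = f"{gene}_{sp}"
            if cell.retro:
                model = make_model(
                    sp, gid, cds_introns=0,
                    utr_introns=1 if gene in utr_only else 0,
                    flank_left=(f"{gene}_newL",),
                    flank_right=(f"{gene}_newR",),
                )
            else:
                model = make_model(
                    sp, gid, cds_introns=2,
                    flank_left=(f"{gene}_ancL",),
                    flank_right=(f"{gene}_ancR",),
                )
            fam.members.setdefault(sp, []).append(model)
            g2f[gid] = gene
        families.append(fam)
    return OrthologCohort(families=families, gene_to_family=g2f)
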