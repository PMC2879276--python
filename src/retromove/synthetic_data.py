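"""Closed-loop synthetic data: ortholog cohorts with planted relocations and
replicate-level expression with planted sex effects.

The generator emulates the statistical structure the analysis assumes: a
retroposition event picks its source element proportionally to dosage-
weighted gene counts, its target proportionally to euchromatin size of the
other elements, and its branch uniformly over the species tree; species
below the branch carry only the intronless copy at the target location
(the parental copy is lost), all other species only the intron-bearing copy
at the source.  Flanking genes are laid out so that an intact-neighborhood
event is confirmable from flanking orthologs, while a fragmented assembly is
emulated by writing the relocated copy onto a short orphan scaffold with no
neighbors.  Expression replicates are Gaussian around a baseline with a
planted sex effect for a configurable fraction of genes.

Every random draw descends from a single root seed via named child streams,
so identically-configured runs are byte-identical on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from . import data_io
from .ancestral_movement import (
    classify_movement,
    count_movements,
    infer_all_events,
    node_label,
)
from .null_model_stats import (
    NullModelConfig,
    class_probabilities,
    chi_square_test,
    expected_counts,
    load_default_null_config,
    multinomial_mc_test,
)
from .retrogene_calling import retained_families, screen
from .types import (
    GeneModel,
    LocationCell,
    LocationMatrix,
    MovementEvent,
    MullerMap,
    OrthologCohort,
    OrthologSet,
    RetromoveError,
)

_GENE_SPAN = 900  # bp footprint of an intron-bearing 3-exon gene
_SPACING = 10_000  # fixed inter-gene spacing on synthetic scaffolds


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the analyzed cohort: 46 candidate families (the size of
    the screened candidate set), an event in half of them, flanking
    neighborhoods intact for ~45% of events (the fraction that survived
    flanking confirmation in the real screen), and microarray-like
    expression with 4 replicates per sex, a 1.0 log2-unit sex effect, 0.5 SD
    noise, and ~30% of genes sex-biased (the share of significant cells in
    the study matrix).
    """

    seed: int = 0
    n_families: int = 46
    event_prob: float = 0.5
    class_probs: Optional[Mapping[str, float]] = None
    neighborhood_intact: float = 0.45
    effect_size: float = 1.0
    reps_per_sex: int = 4
    noise_sd: float = 0.5
    biased_fraction: float = 0.3
    null: NullModelConfig = field(default_factory=load_default_null_config)

    def __post_init__(self) -> None:
        for name in ("event_prob", "neighborhood_intact", "biased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.reps_per_sex < 2:
            raise ValueError("reps_per_sex must be >= 2")


@dataclass
class GroundTruth:
    """Planted truth, consistent with the emitted files."""

    seed: int
    events: dict[str, dict]  # family -> {event, source, target, branch, ...}
    expression_classes: dict[str, dict[str, str]] = field(default_factory=dict)

    def event_families(self) -> list[str]:
        return sorted(f for f, e in self.events.items() if e["event"])

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "events": self.events,
            "expression_classes": self.expression_classes,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GroundTruth":
        return cls(
            seed=int(doc["seed"]),
            events={k: dict(v) for k, v in doc["events"].items()},
            expression_classes={
                g: dict(v) for g, v in doc.get("expression_classes", {}).items()
            },
        )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    cohort: OrthologCohort
    locations: LocationMatrix
    truth: GroundTruth
    species: tuple[str, ...]
    # full per-species gene layout (family copies + background fillers), the
    # exact content the GFF3 writer emits
    layout: dict[str, list[dict]] = field(default_factory=dict)


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw(rng: np.random.Generator, items: Sequence[str], probs) -> str:
    p = np.asarray(probs, dtype=float)
    return items[int(rng.choice(len(items), p=p / p.sum()))]


def _tree_edges(tree: dendropy.Tree) -> list[tuple[str, tuple[str, ...]]]:
    """(branch label, species below) for every non-root branch."""
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = tuple(
            sorted(l.taxon.label.replace(" ", "_") for l in node.leaf_iter())
        )
        edges.append((node_label(node), below))
    return edges


def _sample_source_target(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, str]:
    null = cfg.null
    els = list(null.elements)
    if cfg.class_probs is None:
        wg = [null.weights.get(e, 1.0) * null.gene_counts[e] for e in els]
        src = _draw(rng, els, wg)
        others = [e for e in els if e != src]
        tgt = _draw(rng, others, [null.sizes_mb[e] for e in others])
        return src, tgt
    # class-first sampling: draw the class, then a pair within it with
    # model-proportional weight
    pair_w: dict[str, list[tuple[str, str, float]]] = {}
    wg = {e: null.weights.get(e, 1.0) * null.gene_counts[e] for e in els}
    total_s = sum(null.sizes_mb.values())
    for i in els:
        for j in els:
            if i == j:
                continue
            w = wg[i] * null.sizes_mb[j] / (total_s - null.sizes_mb[i])
            pair_w.setdefault(null.pair_class(i, j), []).append((i, j, w))
    classes = sorted(cfg.class_probs)
    for c in classes:
        if cfg.class_probs[c] > 0 and c not in pair_w:
            raise RetromoveError(f"class {c} has no element pairs")
    cls = _draw(rng, classes, [cfg.class_probs[c] for c in classes])
    pairs = pair_w[cls]
    k = int(rng.choice(len(pairs), p=np.array([w for _, _, w in pairs])
                       / sum(w for _, _, w in pairs)))
    return pairs[k][0], pairs[k][1]


def simulate_ortholog_sets(
    cfg: SimulationConfig,
    tree: Optional[dendropy.Tree] = None,
    muller_map: Optional[MullerMap] = None,
) -> SimulatedCohort:
    """Generate an ortholog cohort with planted retroposition events."""
    tree = tree or data_io.load_default_tree()
    muller_map = muller_map or data_io.load_default_muller_map()
    species = data_io.tree_leaf_labels(tree)
    rngs = _streams(cfg.seed, ["home", "event", "pair", "branch", "intact",
                               "strand"])
    edges = _tree_edges(tree)
    els = list(cfg.null.elements)
    wg = [cfg.null.weights.get(e, 1.0) * cfg.null.gene_counts[e] for e in els]

    fam_ids = [f"FAM{i:04d}" for i in range(cfg.n_families)]
    homes = {f: _draw(rngs["home"], els, wg) for f in fam_ids}
    truth_events: dict[str, dict] = {}
    for f in fam_ids:
        has_event = bool(rngs["event"].random() < cfg.event_prob)
        entry: dict = {"event": has_event, "source": homes[f]}
        if has_event:
            src, tgt = _sample_source_target(rngs["pair"], cfg)
            homes[f] = src
            entry["source"] = src
            entry["target"] = tgt
            branch, below = edges[int(rngs["branch"].integers(len(edges)))]
            entry["branch"] = branch
            entry["species_below"] = list(below)
            entry["intact"] = bool(
                rngs["intact"].random() < cfg.neighborhood_intact
            )
            ev = MovementEvent(
                gene=f, source=src, target=tgt, event_branch=branch,
                single_origin=True, basis="copy-type flags",
                context_species=below,
            )
            entry["movement_class"] = classify_movement(ev, muller_map)
        truth_events[f] = entry

    # scaffold layout: per element, resident slot per family homed there (in
    # family order); relocated copies insert between dedicated background
    # filler genes so their flanking context is consistent across species
    slot_of: dict[str, int] = {}
    per_element_count: dict[str, int] = {e: 0 for e in els}
    for f in fam_ids:
        e = homes[f]
        slot_of[f] = per_element_count[e]
        per_element_count[e] += 1
    insert_slot: dict[str, int] = {}
    per_element_insert: dict[str, int] = {e: 0 for e in els}
    for f in fam_ids:
        ent = truth_events[f]
        if ent["event"] and ent["intact"]:
            tgt = ent["target"]
            insert_slot[f] = per_element_insert[tgt]
            per_element_insert[tgt] += 1

    strands = {f: ("+" if rngs["strand"].random() < 0.5 else "-")
               for f in fam_ids}

    # build per-species gene models directly (the GFF3 writer emits the same
    # structure; data_io round-trips it)
    genes_by_scaffold: dict[tuple[str, str], list[dict]] = {}

    def place(species_: str, scaffold: str, gene_id: str, start: int,
              intronless: bool, strand: str) -> None:
        genes_by_scaffold.setdefault((species_, scaffold), []).append(
            {"gene_id": gene_id, "start": start, "intronless": intronless,
             "strand": strand}
        )

    for sp in species:
        for f in fam_ids:
            ent = truth_events[f]
            relocated = ent["event"] and sp in ent.get("species_below", ())
            gid = f"{f}_{sp}"
            if not relocated:
                e = homes[f]
                start = 1 + slot_of[f] * _SPACING
                place(sp, f"{sp}_scaf_{e}", gid, start, False, strands[f])
            else:
                tgt = ent["target"]
                if ent["intact"]:
                    base = 1 + (per_element_count[tgt] + 1) * _SPACING
                    pos = base + insert_slot[f] * 3 * _SPACING
                    scaffold = f"{sp}_scaf_{tgt}"
                    place(sp, scaffold, f"BG_{f}_L", pos, False, "+")
                    place(sp, scaffold, gid, pos + _SPACING, True, strands[f])
                    place(sp, scaffold, f"BG_{f}_R", pos + 2 * _SPACING,
                          False, "+")
                else:
                    place(sp, f"{sp}_orphan_{f}", gid, 1, True, strands[f])

    # filler genes next to intact insertion sites exist in ALL species so
    # parental-side species also show the background context
    for f, ent in truth_events.items():
        if not (ent["event"] and ent["intact"]):
            continue
        tgt = ent["target"]
        base = 1 + (per_element_count[tgt] + 1) * _SPACING
        pos = base + insert_slot[f] * 3 * _SPACING
        for sp in species:
            if sp in ent["species_below"]:
                continue
            scaffold = f"{sp}_scaf_{tgt}"
            place(sp, scaffold, f"BG_{f}_L", pos, False, "+")
            place(sp, scaffold, f"BG_{f}_R", pos + 2 * _SPACING, False, "+")

    # materialize GeneModel objects with flanks from coordinate order
    families = {f: OrthologSet(family_id=f) for f in fam_ids}
    gene_to_family: dict[str, str] = {}
    for (sp, scaffold), entries in genes_by_scaffold.items():
        entries.sort(key=lambda d: d["start"])
        order = [d["gene_id"] for d in entries]
        for i, d in enumerate(entries):
            left = tuple(reversed(order[max(0, i - 2):i]))
            right = tuple(order[i + 1:i + 3])
            fam = d["gene_id"].rsplit("_", 1)[0]
            if fam not in families:
                continue  # background filler
            model = GeneModel(
                species=sp, gene_id=d["gene_id"], scaffold=scaffold,
                strand=d["strand"], start=d["start"],
                end=d["start"] + (_GENE_SPAN - 1 if not d["intronless"] else 599),
                cds_introns=0 if d["intronless"] else 2,
                flank_left=left, flank_right=right,
            )
            families[fam].members.setdefault(sp, []).append(model)
            gene_to_family[d["gene_id"]] = fam
    cohort = OrthologCohort(
        families=[families[f] for f in fam_ids],
        gene_to_family=gene_to_family,
    )

    # location matrix mirrors the emitted cohort
    cells: dict[str, dict[str, LocationCell]] = {}
    for f in fam_ids:
        ent = truth_events[f]
        row = {}
        for sp in species:
            relocated = ent["event"] and sp in ent.get("species_below", ())
            if relocated:
                row[sp] = LocationCell(states=(ent["target"],), retro=True)
            else:
                row[sp] = LocationCell(states=(homes[f],))
        cells[f] = row
    locations = LocationMatrix(species=tuple(species), cells=cells)

    layout: dict[str, list[dict]] = {sp: [] for sp in species}
    for (sp, scaffold), entries in sorted(genes_by_scaffold.items()):
        for d in entries:
            layout[sp].append({**d, "scaffold": scaffold})

    truth = GroundTruth(seed=cfg.seed, events=truth_events)
    return SimulatedCohort(
        config=cfg, cohort=cohort, locations=locations, truth=truth,
        species=tuple(species), layout=layout,
    )


# ---------------------------------------------------------------------------
# file emission


def _gff3_lines(models: list[dict]) -> list[str]:
    lines = ["##gff-version 3"]
    for d in sorted(models, key=lambda m: (m["scaffold"], m["start"])):
        gid, scaf, start, strand = (
            d["gene_id"], d["scaffold"], d["start"], d["strand"]
        )
        if d["intronless"]:
            end = start + 599
            exons = [(start, end)]
        else:
            end = start + _GENE_SPAN - 1
            exons = [
                (start, start + 199),
                (start + 300, start + 549),
                (start + 650, start + 899),
            ]
        mid = f"{gid}.t1"
        lines.append("\t".join([scaf, "retromove_sim", "gene", str(start),
                                str(end), ".", strand, ".", f"ID={gid}"]))
        lines.append("\t".join([scaf, "retromove_sim", "mRNA", str(start),
                                str(end), ".", strand, ".",
                                f"ID={mid};Parent={gid}"]))
        for i, (s, e) in enumerate(exons, 1):
            lines.append("\t".join([scaf, "retromove_sim", "exon", str(s),
                                    str(e), ".", strand, ".",
                                    f"ID={mid}.exon{i};Parent={mid}"]))
            lines.append("\t".join([scaf, "retromove_sim", "CDS", str(s),
                                    str(e), ".", strand, "0",
                                    f"ID={mid}.cds{i};Parent={mid}"]))
    return lines


def write_simulation(sim: SimulatedCohort, outdir: Path | str) -> dict[str, Path]:
    """Write the cohort as per-species GFF3, ortholog TSV, location-matrix
    TSV and ground-truth JSON; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    per_species = sim.layout
    paths: dict[str, Path] = {}
    for sp in sim.species:
        p = out / f"{sp}.gff3"
        p.write_text("\n".join(_gff3_lines(per_species[sp])) + "\n",
                     encoding="utf-8")
        paths[f"gff:{sp}"] = p
    ortho = out / "orthologs.tsv"
    rows = ["family\tspecies\tgene"]
    for fam in sim.cohort.families:
        for sp in sim.species:
            for m in fam.members.get(sp, []):
                rows.append(f"{fam.family_id}\t{sp}\t{m.gene_id}")
    ortho.write_text("\n".join(rows) + "\n", encoding="utf-8")
    paths["orthologs"] = ortho
    loc = out / "locations.tsv"
    data_io.write_location_matrix(sim.locations, loc)
    paths["locations"] = loc
    tr = out / "truth.json"
    tr.write_text(
        json.dumps(sim.truth.as_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    paths["truth"] = tr
    return paths


def read_simulation(outdir: Path | str) -> tuple[OrthologCohort, LocationMatrix, GroundTruth]:
    """Re-read an emitted simulation directory through the standard readers."""
    out = Path(outdir)
    gffs = {p.stem: p for p in sorted(out.glob("*.gff3"))}
    cohort = data_io.read_gene_models(gffs, out / "orthologs.tsv")
    locations = data_io.read_location_matrix(out / "locations.tsv")
    truth = GroundTruth.from_dict(
        json.loads((out / "truth.json").read_text(encoding="utf-8"))
    )
    return cohort, locations, truth


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    cfg: SimulationConfig,
    genes: Sequence[str],
    species: Sequence[str],
    baseline: float = 5.0,
) -> tuple[dict[tuple[str, str], tuple[list[float], list[float]]], dict[str, dict[str, str]]]:
    """Replicate-level expression with planted per-gene sex effects.

    A planted gene carries the same direction of bias in every species
    (male or female with equal probability); replicate values are
    baseline +/- effect/2 plus Gaussian noise.  Returns the replicate table
    and the per-cell truth classes.
    """
    rngs = _streams(cfg.seed, ["bias", "noise"])
    replicates: dict[tuple[str, str], tuple[list[float], list[float]]] = {}
    truth: dict[str, dict[str, str]] = {}
    r = cfg.reps_per_sex
    for g in genes:
        biased = rngs["bias"].random() < cfg.biased_fraction
        direction = 1.0 if rngs["bias"].random() < 0.5 else -1.0
        truth[g] = {}
        for sp in species:
            shift = (cfg.effect_size / 2.0) * direction if biased else 0.0
            male = baseline + shift + rngs["noise"].normal(0, cfg.noise_sd, r)
            female = baseline - shift + rngs["noise"].normal(0, cfg.noise_sd, r)
            replicates[(g, sp)] = (
                [float(v) for v in male], [float(v) for v in female]
            )
            truth[g][sp] = (
                "unbiased" if not biased
                else ("male" if direction > 0 else "female")
            )
    return replicates, truth


# ---------------------------------------------------------------------------
# end-to-end recovery


def end_to_end_recovery(
    cfg: SimulationConfig,
    tree: Optional[dendropy.Tree] = None,
    muller_map: Optional[MullerMap] = None,
    mc_reps: Optional[int] = None,
) -> dict:
    """Simulate a cohort, run the full screen -> event inference ->
    classification -> heterogeneity test pipeline, and score it against the
    planted truth."""
    tree = tree or data_io.load_default_tree()
    muller_map = muller_map or data_io.load_default_muller_map()
    sim = simulate_ortholog_sets(cfg, tree, muller_map)
    calls, summary = screen(sim.cohort)
    kept = set(retained_families(calls))

    truth_ev = sim.truth.events
    confirmable = {
        f for f, e in truth_ev.items() if e["event"] and e.get("intact")
    }
    planted = {f for f, e in truth_ev.items() if e["event"]}
    tp = len(kept & confirmable)
    fp = len(kept - planted)
    sensitivity = tp / len(confirmable) if confirmable else float("nan")
    negatives = set(truth_ev) - confirmable
    specificity = (
        len(negatives - kept) / len(negatives) if negatives else float("nan")
    )

    events, rejected = infer_all_events(sim.locations, tree, muller_map)
    events = [ev for ev in events if ev.gene in kept]
    direction_hits = sum(
        1
        for ev in events
        if ev.gene in planted
        and ev.source == truth_ev[ev.gene]["source"]
        and ev.target == truth_ev[ev.gene]["target"]
    )
    direction_accuracy = direction_hits / len(events) if events else float("nan")

    observed = count_movements(events, muller_map)
    expected = expected_counts(cfg.null, len(events))
    # observed counts for the test are partitioned under the null config's
    # karyotype (context-aware classes can place an event on a lineage
    # neo-X, a class the configured null has no pairs for)
    obs_test = {c: 0 for c in expected}
    for ev in events:
        obs_test[cfg.null.pair_class(ev.source, ev.target)] += 1
    truth_counts = {c: 0 for c in expected}
    for f in kept & planted:
        e = truth_ev[f]
        truth_counts[cfg.null.pair_class(e["source"], e["target"])] += 1
    class_count_error = sum(
        abs(obs_test[c] - truth_counts[c]) for c in expected
    )
    if mc_reps:
        result = multinomial_mc_test(obs_test, cfg.null, reps=mc_reps,
                                     seed=cfg.seed)
    elif len(events):
        result = chi_square_test(obs_test, expected)
    else:
        result = None
    return {
        "screen_summary": summary.as_dict(),
        "n_retained": len(kept),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "direction_accuracy": direction_accuracy,
        "observed_counts": obs_test,
        "truth_counts": truth_counts,
        "class_count_error": class_count_error,
        "chi2": None if result is None else result.statistic,
        "pvalue": None if result is None else result.pvalue,
        "mc_pvalue": None if result is None else result.mc_pvalue,
        "rejected": rejected,
    }
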