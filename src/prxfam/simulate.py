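"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the four data sources the analysis consumes:

* a tissue-structured log2 expression compendium with planted
  co-expression blocks and tissue-preferential effects,
* promoter sets with group-specific motifs planted over an i.i.d.
  background nucleotide model (cross-group purity enforced),
* a protein family evolved by Poisson substitutions on a known
  4-clade tree,
* a hub-structured interaction edge table with functional classes.

Every generator is a pure function of a :class:`SynthConfig`: the same
config and seed give byte-identical artifacts. Each returns its outputs
together with a :class:`TruthBundle` recording what was planted, so
downstream recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree

from .expression import ExpressionMatrix
from .motifs import (
    IUPAC_CODES,
    MotifLibrary,
    MotifRecord,
    PromoterRecord,
    PromoterSet,
    scan_sequence,
)
from .network import CLASS_VOCABULARY, InteractionTable
from .phylo import AlignedProteinSet, write_newick

#: The default motif library: 13 named IUPAC consensi of plant CREs.
REFERENCE_MOTIFS: tuple[tuple[str, str], ...] = (
    ("ABREDISTBBNNAPA", "GCCACTTGTC"),
    ("ABREAZMRAB28", "GCCACGTGGG"),
    ("ABREBZMRAB28", "TCCACGTCTC"),
    ("ABREOSRAB21", "ACGTSSSC"),
    ("GADOWNAT", "ACGTGTC"),
    ("TATCCAYMOTIFOSRAMY3D", "TATCCAY"),
    ("TATCCAOSAMY", "TATCCA"),
    ("PBOX1", "TGRAAG"),
    ("GAREAT", "TAACAAR"),
    ("GARE1OSREP1", "TAACAGA"),
    ("OSE1ROOTNODULE", "AAAGAT"),
    ("LEAFYATAG", "CCAATGT"),
    ("WUSATAg", "TTAATGG"),
)

#: Seed/endosperm-associated motifs planted in group A by default.
GROUP_A_CANDIDATES = (
    "TATCCAYMOTIFOSRAMY3D",
    "GADOWNAT",
    "ABREDISTBBNNAPA",
    "ABREAZMRAB28",
    "ABREBZMRAB28",
    "ABREOSRAB21",
    "TATCCAOSAMY",
)

#: Root/embryo-associated motifs planted in group B by default.
GROUP_B_CANDIDATES = (
    "PBOX1",
    "GAREAT",
    "GARE1OSREP1",
    "OSE1ROOTNODULE",
    "LEAFYATAG",
    "WUSATAg",
)

DEFAULT_TISSUES = ("leaf", "shoot", "root", "flower", "pollen", "seed")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """A SynthConfig field violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study, with the defaults the package
    treats as its reference conditions.

    Expression: 6 tissues, 3 replicate arrays each, intensities clipped
    to [5, 15] log2 units (array saturation), a 4 log2 tissue-
    preferential boost over per-sample noise of SD 0.5. Promoters: 2 kb
    of i.i.d. background at GC 0.44 with group motifs inserted. Protein
    family: 20 taxa in 4 clades, Poisson substitutions. Interactions:
    four hubs of degrees 60/16/3/3.
    """

    seed: int = 0
    n_genes: int = 200
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    reps_per_tissue: int = 3
    intensity_floor: float = 5.0
    intensity_ceiling: float = 15.0
    effect_size: float = 4.0
    noise_sd: float = 0.5
    promoter_length: int = 2000
    gc_content: float = 0.44
    group_sizes: tuple[int, int] = (5, 6)
    planted_motifs_per_group: int = 2
    n_decoy_motifs: int = 10
    hub_degrees: tuple[int, ...] = (60, 16, 3, 3)
    hub_overlap: float = 0.0
    coexpressed_per_hub: tuple[int, ...] = (12, 3, 0, 2)
    n_clades: int = 4
    taxa_per_clade: int = 5
    n_sites: int = 300
    within_clade_rate: float = 0.05
    between_clade_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.intensity_floor >= self.intensity_ceiling:
            raise ConfigurationError("intensity floor must be below ceiling")
        for name in ("n_genes", "reps_per_tissue", "promoter_length",
                     "taxa_per_clade", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ConfigurationError("gc_content must be in [0, 1]")
        if any(s < 1 for s in self.group_sizes):
            raise ConfigurationError("group sizes must be >= 1")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ConfigurationError("noise_sd and effect_size must be >= 0")
        if len(self.tissues) < 2:
            raise ConfigurationError("need at least 2 tissues")
        if self.n_clades < 4:
            raise ConfigurationError("need at least 4 subgroup clades")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named output stream."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=tuple(ord(c) for c in stream)
        )
        return np.random.default_rng(ss)


@dataclass
class TruthBundle:
    """Ground truth recorded at generation time.

    Only the fields a given generator owns are filled; the pipeline
    merges bundles from the generators it ran.
    """

    planted_motifs: dict[str, list[str]] = field(default_factory=dict)
    planted_positions: dict[str, list[tuple[str, int, str]]] = field(
        default_factory=dict
    )
    coexpr_blocks: dict[str, list[str]] = field(default_factory=dict)
    expression_classes: dict[str, tuple[str, str | None]] = field(
        default_factory=dict
    )
    true_tree_newick: str = ""
    clade_membership: dict[str, str] = field(default_factory=dict)
    hub_partners: dict[str, list[str]] = field(default_factory=dict)

    def merge(self, other: "TruthBundle") -> "TruthBundle":
        merged = TruthBundle()
        for f in dataclasses.fields(TruthBundle):
            a = getattr(self, f.name)
            b = getattr(other, f.name)
            if isinstance(a, dict):
                setattr(merged, f.name, {**a, **b})
            else:
                setattr(merged, f.name, b or a)
        return merged

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, default=list)


def group_gene_ids(config: SynthConfig) -> tuple[list[str], list[str]]:
    """Deterministic ids of the two planted block/group members.

    The first member of each block is the bait (the family gene whose
    co-expression neighbourhood defines the group).
    """
    a = [f"blkA_g{i + 1}" for i in range(config.group_sizes[0])]
    b = [f"blkB_g{i + 1}" for i in range(config.group_sizes[1])]
    return a, b


# ---------------------------------------------------------------------------
# expression compendium


def gen_expression_compendium(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, TruthBundle]:
    """Tissue-structured log2 compendium with two planted blocks.

    Block A shares a seed-preferential tissue-mean profile, block B a
    root-preferential one; members add independent per-sample noise.
    Background genes are ~20% tissue-preferential (random tissue),
    ~60% ubiquitous and ~20% suppressed; all values clip to
    [floor, ceiling].
    """
    if config.reps_per_tissue < 1:
        raise ConfigurationError("reps_per_tissue must be >= 1")
    rng = config.rng("expression")
    tissues = list(config.tissues)
    samples = [
        f"{t}_r{r + 1}" for t in tissues for r in range(config.reps_per_tissue)
    ]
    sample_tissue = [t for t in tissues for _ in range(config.reps_per_tissue)]

    ids_a, ids_b = group_gene_ids(config)
    n_bg = max(config.n_genes - len(ids_a) - len(ids_b), 0)
    bg_ids = [f"bg_{i + 1:04d}" for i in range(n_bg)]
    gene_ids = ids_a + ids_b + bg_ids

    truth = TruthBundle()
    truth.coexpr_blocks = {ids_a[0]: list(ids_a), ids_b[0]: list(ids_b)}

    pref_a = "seed" if "seed" in tissues else tissues[-1]
    pref_b = "root" if "root" in tissues else tissues[0]

    def block_profile(preferred: str) -> dict[str, float]:
        base = float(rng.uniform(7.0, 9.0))
        return {
            t: base + (config.effect_size if t == preferred else 0.0)
            for t in tissues
        }

    profiles: dict[str, dict[str, float]] = {}
    prof_a = block_profile(pref_a)
    prof_b = block_profile(pref_b)
    for g in ids_a:
        profiles[g] = prof_a
        truth.expression_classes[g] = ("tissue-preferential", pref_a)
    for g in ids_b:
        profiles[g] = prof_b
        truth.expression_classes[g] = ("tissue-preferential", pref_b)

    # block tissues are reserved so block membership stays identifiable:
    # a background gene boosted in the same tissue would duplicate the
    # block's profile shape and make the planted truth ambiguous
    free_tissues = [t for t in tissues if t not in (pref_a, pref_b)]
    for g in bg_ids:
        u = float(rng.uniform())
        if u < 0.2:  # preferential in a random non-block tissue
            pref = free_tissues[int(rng.integers(len(free_tissues)))]
            base = float(rng.uniform(7.0, 9.0))
            profiles[g] = {
                t: base + (config.effect_size if t == pref else 0.0)
                for t in tissues
            }
            truth.expression_classes[g] = ("tissue-preferential", pref)
        elif u < 0.8:  # ubiquitous
            base = float(rng.uniform(8.0, 12.0))
            profiles[g] = {t: base for t in tissues}
            truth.expression_classes[g] = ("ubiquitous", None)
        else:  # suppressed: below the detection floor everywhere
            base = float(rng.uniform(config.intensity_floor, 5.8))
            profiles[g] = {t: base for t in tissues}
            truth.expression_classes[g] = ("suppressed", None)

    values = np.empty((len(gene_ids), len(samples)))
    for i, g in enumerate(gene_ids):
        means = np.array([profiles[g][t] for t in sample_tissue])
        noise = rng.normal(0.0, config.noise_sd, size=len(samples))
        values[i] = np.clip(
            means + noise, config.intensity_floor, config.intensity_ceiling
        )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        tissue_map=pd.Series(sample_tissue, index=samples),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# motif library


def gen_motif_library(n_decoys: int, seed: int = 0) -> MotifLibrary:
    """The 13 reference consensi plus ``n_decoys`` random IUPAC decoys.

    Decoy consensi are 6-10 symbols, mostly concrete bases with
    occasional two-fold degenerate codes, so their information content
    resembles the real library's.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    records = [MotifRecord(name, cons) for name, cons in REFERENCE_MOTIFS]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    degenerate = "RYSWKM"
    existing = {c for _, c in REFERENCE_MOTIFS}
    i = 0
    while len(records) < len(REFERENCE_MOTIFS) + n_decoys:
        length = int(rng.integers(6, 11))
        syms = []
        for _ in range(length):
            if rng.uniform() < 0.85:
                syms.append("ACGT"[int(rng.integers(4))])
            else:
                syms.append(degenerate[int(rng.integers(6))])
        cons = "".join(syms)
        if cons in existing:
            continue
        existing.add(cons)
        i += 1
        records.append(MotifRecord(f"DECOY{i:02d}", cons))
    return MotifLibrary(records)


# ---------------------------------------------------------------------------
# promoter sets


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _realise(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        sorted(IUPAC_CODES[s])[int(rng.integers(len(IUPAC_CODES[s])))]
        for s in consensus.upper()
    )


def _forbidden_hits(seq: str, forbidden: list[MotifRecord]):
    rec = PromoterRecord(gene_id="_tmp", sequence=seq)
    hits = []
    for m in forbidden:
        hits.extend(scan_sequence(rec, m, strands="both"))
    return hits


def default_planted_motifs(
    config: SynthConfig, library: MotifLibrary
) -> tuple[list[str], list[str]]:
    """Default disjoint planted sets: seed-associated motifs for group A,
    root/embryo-associated for group B."""
    k = config.planted_motifs_per_group
    if k > len(GROUP_A_CANDIDATES) or k > len(GROUP_B_CANDIDATES):
        raise ConfigurationError(
            "planted_motifs_per_group exceeds the candidate motif lists"
        )
    a = [n for n in GROUP_A_CANDIDATES[:k] if n in library]
    b = [n for n in GROUP_B_CANDIDATES[:k] if n in library]
    if len(a) < k or len(b) < k:
        raise ConfigurationError("library lacks the default planted motifs")
    return a, b


def gen_promoter_set(
    config: SynthConfig,
    library: MotifLibrary,
    planted_a: list[str] | None = None,
    planted_b: list[str] | None = None,
    max_redraws: int = 10_000,
) -> tuple[PromoterSet, TruthBundle]:
    """Two groups of background promoters with group motifs planted.

    Each promoter is ``promoter_length`` bp of i.i.d. background at the
    configured GC. Every motif of the promoter's group is inserted once
    at a random non-overlapping position (a concrete realisation of its
    consensus). Accidental hits of the *other* group's planted motifs
    are removed by resampling only the offending background window —
    planted sites are never edited — and the promoter is rescanned until
    clean, so cross-group purity holds exactly.
    """
    if planted_a is None or planted_b is None:
        da, db = default_planted_motifs(config, library)
        planted_a = planted_a if planted_a is not None else da
        planted_b = planted_b if planted_b is not None else db
    if set(planted_a) & set(planted_b):
        raise ConfigurationError("planted motif sets must be disjoint")
    for name in [*planted_a, *planted_b]:
        if name not in library:
            raise KeyError(f"planted motif {name!r} not in library")
        if len(library[name].consensus) > config.promoter_length:
            raise ConfigurationError(
                f"motif {name!r} longer than the promoter"
            )

    rng = config.rng("promoters")
    ids_a, ids_b = group_gene_ids(config)
    truth = TruthBundle()
    truth.planted_motifs = {"A": list(planted_a), "B": list(planted_b)}

    records: list[PromoterRecord] = []
    for gene_ids, own, other in (
        (ids_a, planted_a, planted_b),
        (ids_b, planted_b, planted_a),
    ):
        own_recs = [library[n] for n in own]
        other_recs = [library[n] for n in other]
        for gene in gene_ids:
            seq, placements = _build_promoter(
                rng, config, own_recs, other_recs, max_redraws
            )
            records.append(PromoterRecord(gene_id=gene, sequence=seq))
            truth.planted_positions[gene] = placements

    promoters = PromoterSet(records)
    _verify_planting(promoters, library, truth)
    return promoters, truth


def _build_promoter(rng, config, own_recs, other_recs, max_redraws):
    length = config.promoter_length
    for _ in range(max_redraws):
        arr = _background(rng, length, config.gc_content)
        protected = np.zeros(length, dtype=bool)
        placements: list[tuple[str, int, str]] = []
        ok = True
        for rec in own_recs:
            w = len(rec.consensus)
            # non-overlapping slot for the planted realisation
            for _ in range(1000):
                start = int(rng.integers(0, length - w + 1))
                if not protected[start : start + w].any():
                    break
            else:
                ok = False
                break
            word = _realise(rng, rec.consensus)
            arr[start : start + w] = list(word)
            protected[start : start + w] = True
            placements.append((rec.name, start, "+"))
        if not ok:
            continue
        if _purify(rng, arr, protected, other_recs, config, max_redraws):
            return "".join(arr), placements
    raise RuntimeError("promoter generation failed to converge")


def _purify(rng, arr, protected, other_recs, config, max_iters) -> bool:
    """Resample background windows until no forbidden-motif hit remains."""
    for _ in range(max_iters):
        hits = _forbidden_hits("".join(arr), other_recs)
        if not hits:
            return True
        fixed_any = False
        for h in hits:
            span = slice(h.start, h.start + len(h.matched))
            free = ~protected[span]
            if not free.any():
                return False  # hit sits wholly inside planted sites: redraw promoter
            repl = _background(rng, int(free.sum()), config.gc_content)
            window = arr[span]
            window[free] = repl
            arr[span] = window
            fixed_any = True
        if not fixed_any:
            return False
    return False


def _verify_planting(
    promoters: PromoterSet, library: MotifLibrary, truth: TruthBundle
) -> None:
    """Post-generation scan: planted pairs present, cross-group pure."""
    groups = truth.planted_motifs
    for label, motifs in groups.items():
        other_label = "B" if label == "A" else "A"
        members = [
            g for g in truth.planted_positions if g.startswith(f"blk{label}_")
        ]
        for g in members:
            rec = promoters[g]
            for name in motifs:
                hits = scan_sequence(rec, library[name], strands="both")
                starts = {h.start for h in hits}
                planted = {
                    s for n, s, _ in truth.planted_positions[g] if n == name
                }
                if not planted <= starts:
                    raise AssertionError(
                        f"planted {name} not recovered in {g}"
                    )
            for name in groups[other_label]:
                if scan_sequence(rec, library[name], strands="both"):
                    raise AssertionError(
                        f"cross-group motif {name} present in {g}"
                    )


# ---------------------------------------------------------------------------
# protein family


def _true_family_tree(config: SynthConfig) -> tuple[Tree, dict[str, str]]:
    """Balanced unrooted tree: clades on long stems off a central path."""
    wr, br = config.within_clade_rate, config.between_clade_rate
    membership: dict[str, str] = {}
    clade_roots = []
    for c in range(config.n_clades):
        label = f"SG{c + 1}"
        leaves = []
        for t in range(config.taxa_per_clade):
            name = f"{label}_t{t + 1}"
            membership[name] = label
            leaves.append(Clade(name=name, branch_length=wr))
        # caterpillar inside the clade
        node = leaves[0]
        for leaf in leaves[1:]:
            node = Clade(clades=[node, leaf], branch_length=wr)
        node.branch_length = br  # long stem isolating the clade
        clade_roots.append(node)
    # central backbone joining stems pairwise
    backbone = clade_roots[0]
    for nxt in clade_roots[1:-1]:
        backbone = Clade(clades=[backbone, nxt], branch_length=br / 2)
    root = Clade(clades=[backbone, clade_roots[-1]])
    return Tree(root=root, rooted=False), membership


def _evolve(rng, parent: np.ndarray, branch_length: float) -> np.ndarray:
    child = parent.copy()
    n_sub = rng.poisson(branch_length * len(parent))
    sites = rng.integers(0, len(parent), size=n_sub)
    for s in sites:
        choices = [a for a in AMINO_ACIDS if a != child[s]]
        child[s] = choices[int(rng.integers(len(choices)))]
    return child


def gen_protein_family(
    config: SynthConfig,
) -> tuple[AlignedProteinSet, str, TruthBundle]:
    """Protein family evolved on a known 4-clade tree.

    Independent-site Poisson substitutions with uniform replacement;
    no indels, so the emitted FASTA is trivially aligned. Returns the
    aligned set, the true tree in Newick, and the clade membership.
    """
    rng = config.rng("proteins")
    tree, membership = _true_family_tree(config)
    root_seq = np.array(
        [AMINO_ACIDS[int(rng.integers(20))] for _ in range(config.n_sites)],
        dtype="U1",
    )
    seqs: dict[str, str] = {}

    def walk(clade: Clade, seq: np.ndarray) -> None:
        for child in clade.clades:
            bl = child.branch_length or 0.0
            child_seq = _evolve(rng, seq, bl)
            if child.is_terminal():
                seqs[child.name] = "".join(child_seq)
            else:
                walk(child, child_seq)

    walk(tree.root, root_seq)
    ids = sorted(seqs)
    aligned = AlignedProteinSet(ids=ids, rows=[seqs[i] for i in ids])
    newick = write_newick(tree, support_as_int=False)
    truth = TruthBundle()
    truth.true_tree_newick = newick.strip()
    truth.clade_membership = membership
    return aligned, newick.strip(), truth


# ---------------------------------------------------------------------------
# interaction table

HUB_IDS = ("Os2CysPrxA", "OsPrxIIC", "Os1CysPrxA", "OsPrxQ")


def gen_interaction_table(
    config: SynthConfig,
) -> tuple[InteractionTable, TruthBundle]:
    """Hub-and-spoke interaction edge table with functional classes.

    One hub per ``hub_degrees`` entry; partner sets are disjoint by
    default, with ``hub_overlap`` the fraction of each later hub's
    partners recycled from earlier hubs. Partners get rice-locus-style
    ids, a class from the fixed 11-class vocabulary, and a known-
    function flag (three known partners overall, as in curated sets).
    """
    if not config.hub_degrees:
        raise ConfigurationError("hub_degrees must be non-empty")
    rng = config.rng("interactions")
    hubs = [
        HUB_IDS[i] if i < len(HUB_IDS) else f"HUB{i + 1}"
        for i in range(len(config.hub_degrees))
    ]
    used: list[str] = []
    next_locus = 10010
    rows = []
    truth = TruthBundle()
    for hub, degree in zip(hubs, config.hub_degrees):
        n_recycled = int(round(config.hub_overlap * degree))
        n_recycled = min(n_recycled, len(used))
        recycled = (
            list(rng.choice(np.array(used), size=n_recycled, replace=False))
            if n_recycled
            else []
        )
        fresh = []
        for _ in range(degree - n_recycled):
            chrom = int(rng.integers(1, 13))
            locus = f"LOC_Os{chrom:02d}g{next_locus:05d}"
            next_locus += 10
            fresh.append(locus)
        partners = sorted(recycled + fresh)
        truth.hub_partners[hub] = partners
        for p in partners:
            cls = CLASS_VOCABULARY[int(rng.integers(len(CLASS_VOCABULARY)))]
            rows.append({"hub": hub, "partner": p, "class": cls, "known": "false"})
        used.extend(fresh)
    # three partners with characterised functions, as in curated overlays
    known_idx = rng.choice(len(rows), size=min(3, len(rows)), replace=False)
    for i in known_idx:
        rows[int(i)]["known"] = "true"
    table = InteractionTable(edges=pd.DataFrame(rows))
    return table, truth


def gen_interaction_expression(
    config: SynthConfig,
    truth: TruthBundle,
    pcc_margin: float = 0.3,
) -> ExpressionMatrix:
    """Expression profiles for hubs and partners with controlled PCC.

    For each hub, the first ``coexpressed_per_hub[i]`` partners track the
    hub's tissue profile (plus small noise, so their PCC is high); the
    remaining partners get independent profiles, redrawn until their PCC
    with the hub is below ``pcc_margin`` so the >0.5 co-expression calls
    are exactly the configured ones.
    """
    rng = config.rng("interaction-expression")
    tissues = list(config.tissues)
    samples = [
        f"{t}_r{r + 1}" for t in tissues for r in range(config.reps_per_tissue)
    ]
    sample_tissue = [t for t in tissues for _ in range(config.reps_per_tissue)]
    n_s = len(samples)

    hubs = list(truth.hub_partners)
    n_coex = list(config.coexpressed_per_hub) + [0] * len(hubs)
    rows: dict[str, np.ndarray] = {}

    def tissue_profile() -> np.ndarray:
        means = {t: float(rng.uniform(6.0, 12.0)) for t in tissues}
        prof = np.array([means[t] for t in sample_tissue])
        return prof + rng.normal(0.0, config.noise_sd, size=n_s)

    for hub in hubs:
        rows[hub] = tissue_profile()
    for i, hub in enumerate(hubs):
        partners = truth.hub_partners[hub]
        want = min(n_coex[i], len(partners))
        for j, partner in enumerate(partners):
            if partner in rows:
                continue  # recycled partner already profiled
            if j < want:
                rows[partner] = rows[hub] + rng.normal(
                    0.0, config.noise_sd, size=n_s
                )
            else:
                for _ in range(1000):
                    prof = tissue_profile()
                    r = np.corrcoef(prof, rows[hub])[0, 1]
                    if abs(r) < pcc_margin:
                        rows[partner] = prof
                        break
                else:
                    raise RuntimeError("failed to draw a low-PCC profile")
    values = np.clip(
        np.vstack([rows[g] for g in rows]),
        config.intensity_floor,
        config.intensity_ceiling,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=list(rows), columns=samples),
        tissue_map=pd.Series(sample_tissue, index=samples),
    )


# ---------------------------------------------------------------------------
# writers


def write_promoters_fasta(promoters: PromoterSet, fasta_path, bed_path) -> None:
    """Promoters as FASTA plus BED (0-based half-open) region records."""
    with open(fasta_path, "w") as fh:
        for rec in promoters:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for rec in promoters:
            fh.write(
                f"{rec.gene_id}\t0\t{len(rec.sequence)}\t"
                f"{rec.gene_id}_promoter\t0\t+\n"
            )


def write_protein_fasta(aligned: AlignedProteinSet, path) -> None:
    with open(path, "w") as fh:
        for tid, row in zip(aligned.ids, aligned.rows):
            fh.write(f">{tid}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")
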