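"""Synthetic inputs with known ground truth, plus the packaged fixtures.

Everything the pipeline consumes can be generated here: timed trees
carrying a single-gain/irreversible-loss (Dollo) presence character,
keratin-cluster-like locus maps with conserved flanking anchors, coding
models with planted inactivating lesions, and qPCR Ct tables under the
efficiency-2 amplification model with Gaussian cycle noise.  Each
generator returns the emitted object together with a
:class:`GroundTruth` record of what was planted, so recovery can be
asserted exactly.

All randomness flows from a single integer seed through named streams
(:func:`rng_stream`): adding a new generator never perturbs the draws of
an existing one.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coevolution import PairingRules
from .dollo import PresenceMatrix
from .locus import GeneFeature, LocusMap
from .orf import CodingModel
from .trees import ROOT, SpeciesTree

__all__ = [
    "GroundTruth",
    "rng_stream",
    "simulate_dollo_character",
    "mutate_cds",
    "random_intact_cds",
    "shuffle_locus",
    "simulate_qpcr",
    "load_fixture",
    "FIXTURE_NAMES",
]

STOP_CODONS = ("TGA", "TAA", "TAG")
FIXTURE_NAMES = (
    "mammal_tree",
    "krt24_states",
    "fig4_states",
    "human_keratin_locus",
    "tetrapod_locus_maps",
    "pairing_rules",
)


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream named ``name``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class GroundTruth:
    """What a generator actually planted."""

    gain_branch: Optional[str] = None
    loss_branches: frozenset[str] = frozenset()
    lesions: list[tuple] = field(default_factory=list)
    fold_changes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Dollo character process


def simulate_dollo_character(
    tree: SpeciesTree,
    gain_branch: str,
    loss_rate: float,
    seed: int,
) -> tuple[dict[str, str], GroundTruth]:
    """Simulate one gene's presence states under the Dollo process.

    The gene exists from ``gain_branch`` (an edge id, or ``ROOT``)
    downward; on every descendant edge of length t (MY) it is lost with
    probability 1 - exp(-loss_rate * t) and, once lost, stays lost.
    Leaves outside the gain clade are ABSENT; leaves that lost the gene
    are PSEUDOGENE, the rest INTACT.  Ground truth records the maximal
    (highest) loss edges.
    """
    if loss_rate < 0:
        raise ValueError("loss_rate must be >= 0")
    if not tree.has_branch_lengths():
        raise ValueError("tree must have branch lengths")
    gain_node = tree.root if gain_branch == ROOT else gain_branch
    if not tree.has_node(gain_node):
        raise ValueError(f"gain branch {gain_branch!r} not in tree")
    rng = rng_stream(seed, "dollo_character")

    clade = {gain_node} | {
        n for n in tree.preorder() if tree.is_ancestor(gain_node, n)
    }
    present = {gain_node: True}
    loss_edges: set[str] = set()
    for node in tree.preorder():
        if node == gain_node or node not in clade:
            continue
        u = rng.uniform()  # one draw per clade edge, in pre-order
        t = tree.edge_length(node)
        if not present.get(tree.parent(node), False):
            present[node] = False
            continue
        lost = u < 1.0 - math.exp(-loss_rate * t)
        present[node] = not lost
        if lost:
            loss_edges.add(node)

    states = {}
    for leaf in tree.leaves():
        if leaf not in clade:
            states[leaf] = "ABSENT"
        else:
            states[leaf] = "INTACT" if present[leaf] else "PSEUDOGENE"
    truth = GroundTruth(gain_branch=gain_branch, loss_branches=frozenset(loss_edges))
    return states, truth


# ---------------------------------------------------------------------------
# CDS mutation


def random_intact_cds(
    n_codons: int,
    seed: int,
    n_exons: int = 1,
    species: str = "synthetic",
    gene_id: str = "geneX",
) -> CodingModel:
    """An intact ORF: ATG, ``n_codons - 2`` non-stop codons, one stop.

    Exon boundaries split the spliced CDS into ``n_exons`` contiguous
    pieces at deterministic positions (synthetic genomic coordinates are
    simply contiguous).
    """
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    rng = rng_stream(seed, "intact_cds")
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    exons = _contiguous_exons(len(cds), n_exons)
    return CodingModel(
        gene_id=gene_id, species=species, exons=exons, strand="+", spliced_cds=cds
    )


def _contiguous_exons(length: int, n_exons: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, length, n_exons + 1).astype(int)
    return [(int(a) + 1, int(b)) for a, b in zip(cuts[:-1], cuts[1:])]


def mutate_cds(
    model: CodingModel,
    lesion_spec: Sequence[tuple],
    seed: int,
) -> tuple[CodingModel, GroundTruth]:
    """Plant inactivating lesions into an intact coding model.

    ``lesion_spec`` entries:

    * ``("PREMATURE_STOP", codon)`` — substitute the codon by a stop;
    * ``("FRAMESHIFT_INDEL", codon, k)`` — delete (k < 0) or insert
      (k > 0) ``|k|`` nt at the codon start, with ``|k| % 3 != 0``;
    * ``("START_LOSS",)`` — mutate the initial ATG.

    Exon junctions downstream of an indel shift with it; synthetic
    genomic coordinates stay contiguous.  Returns the mutated model and
    the planted lesions as ground truth.
    """
    rng = rng_stream(seed, "mutate_cds")
    cds = model.spliced_cds
    junctions = [sum(e - s + 1 for s, e in model.exons[:k])
                 for k in range(1, len(model.exons))]
    positions = set()
    for spec in lesion_spec:
        codon = spec[1] if len(spec) > 1 else 1
        if codon in positions:
            raise ValueError(f"lesion position collision at codon {codon}")
        positions.add(codon)
        if not (1 <= codon <= len(cds) // 3):
            raise ValueError(f"codon {codon} outside CDS")

    truth = GroundTruth()
    # apply highest position first so earlier codon indices stay valid
    for spec in sorted(lesion_spec, key=lambda s: -(s[1] if len(s) > 1 else 1)):
        kind = spec[0]
        if kind == "PREMATURE_STOP":
            codon = spec[1]
            stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
            at = 3 * (codon - 1)
            cds = cds[:at] + stop + cds[at + 3 :]
            truth.lesions.append(("PREMATURE_STOP", codon))
        elif kind == "FRAMESHIFT_INDEL":
            codon, k = spec[1], spec[2]
            if k == 0 or abs(k) % 3 == 0:
                raise ValueError("frameshift size must not be a multiple of 3")
            at = 3 * (codon - 1)
            if k < 0:
                cds = cds[:at] + cds[at - k :]
                delta = k
            else:
                ins = "".join(rng.choice(list("ACGT"), size=k))
                cds = cds[:at] + ins + cds[at:]
                delta = k
            junctions = [j + delta if j > at else j for j in junctions]
            truth.lesions.append(("FRAMESHIFT_INDEL", codon, k))
        elif kind == "START_LOSS":
            repl = "ATG"
            while repl == "ATG" or repl in STOP_CODONS:
                repl = "".join(rng.choice(list("ACGT"), size=3))
            cds = repl + cds[3:]
            truth.lesions.append(("START_LOSS", 1))
        else:
            raise ValueError(f"unknown lesion kind {kind!r}")

    bounds = [0] + [j for j in junctions if 0 < j < len(cds)] + [len(cds)]
    exons = [(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])]
    truth.lesions.sort(key=lambda l: (l[1] if len(l) > 1 else 1, l[0]))
    mutated = CodingModel(
        gene_id=model.gene_id,
        species=model.species,
        exons=exons,
        strand=model.strand,
        spliced_cds=cds,
        rod_domain=None,
        genetic_code=model.genetic_code,
    )
    return mutated, truth


# ---------------------------------------------------------------------------
# locus shuffling


def shuffle_locus(
    reference: LocusMap,
    ops: Sequence[tuple],
    seed: int = 0,
    anchors: Sequence[str] = (),
) -> LocusMap:
    """Apply an edit script to a locus map, re-spacing coordinates.

    ``ops`` entries: ``("drop", symbol)``, ``("insert", symbol, index)``
    (0-based slot in gene order) and ``("invert", first_symbol,
    last_symbol)`` which reverses the enclosed block and flips strands.
    Dropping a symbol listed in ``anchors`` only warns — downstream
    window calls will then report an incomplete window, as they should.
    """
    genes: list[tuple[str, str]] = [(f.symbol, f.strand) for f in reference.features]

    def index_of(symbol: str) -> int:
        for i, (s, _) in enumerate(genes):
            if s.upper() == symbol.upper():
                return i
        raise KeyError(f"symbol {symbol!r} not in map")

    for op in ops:
        kind = op[0]
        if kind == "drop":
            if op[1].upper() in {a.upper() for a in anchors}:
                warnings.warn(f"dropping anchor gene {op[1]!r}", stacklevel=2)
            genes.pop(index_of(op[1]))
        elif kind == "insert":
            symbol, at = op[1], op[2]
            genes.insert(at, (symbol, "+"))
        elif kind == "invert":
            i, j = index_of(op[1]), index_of(op[2])
            i, j = min(i, j), max(i, j)
            block = [(s, "+" if st == "-" else "-") for s, st in genes[i : j + 1]]
            genes[i : j + 1] = block[::-1]
        else:
            raise ValueError(f"unknown locus op {kind!r}")

    spacing, width = 20_000, 5_000
    feats = [
        GeneFeature(
            gene_id=f"{sym}@{100_000 + i * spacing}",
            symbol=sym,
            species=reference.species,
            sequence_region=reference.sequence_region,
            start=100_000 + i * spacing,
            end=100_000 + i * spacing + width,
            strand=strand,
        )
        for i, (sym, strand) in enumerate(genes)
    ]
    return LocusMap(
        species=reference.species,
        sequence_region=reference.sequence_region,
        features=feats,
    )


# ---------------------------------------------------------------------------
# qPCR tables


def simulate_qpcr(
    fold_by_tissue: Mapping[str, float],
    n_by_tissue: Mapping[str, int],
    noise_sd: float,
    seed: int,
    gene: str = "KRT24",
    reference: str = "GAPDH",
    base_ct: float = 20.0,
    reference_ct: float = 20.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format Ct table under the efficiency-2 model.

    Each sample's target Ct is ``base_ct - log2(fold) + N(0, sd)`` and
    its reference Ct is ``reference_ct + N(0, sd)``, so with sd = 0 the
    target/reference ratio of a tissue equals its fold change exactly
    (for fold 1 and equal baselines, the ratio is 1).
    """
    for tissue, fold in fold_by_tissue.items():
        if fold <= 0:
            raise ValueError(f"fold change for {tissue!r} must be > 0")
    rng = rng_stream(seed, "qpcr")
    rows = []
    for tissue in fold_by_tissue:
        fold = fold_by_tissue[tissue]
        for i in range(n_by_tissue[tissue]):
            sample = f"{tissue}_{i + 1}"
            ct_t = base_ct - math.log2(fold) + rng.normal(0.0, noise_sd)
            ct_r = reference_ct + rng.normal(0.0, noise_sd)
            rows.append(dict(sample_id=sample, tissue=tissue, gene=gene,
                             ct=ct_t, efficiency=2.0))
            rows.append(dict(sample_id=sample, tissue=tissue, gene=reference,
                             ct=ct_r, efficiency=2.0))
    table = pd.DataFrame(rows)
    truth = GroundTruth(fold_changes=dict(fold_by_tissue))
    return table, truth


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_path(*parts: str):
    return resources.files("dollotrace").joinpath("fixtures", *parts)


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Names: ``mammal_tree`` (timed SpeciesTree), ``krt24_states`` and
    ``fig4_states`` (PresenceMatrix), ``human_keratin_locus`` (LocusMap),
    ``tetrapod_locus_maps`` (dict of LocusMap) and ``pairing_rules``
    (PairingRules).  Branch lengths of the tree are approximate MY values
    for dating illustration only.
    """
    from .locus import read_locus_map  # local import to avoid cycle at startup

    if name == "mammal_tree":
        return SpeciesTree.from_newick(_fixture_path("mammal_tree.nwk").read_text())
    if name in ("krt24_states", "fig4_states"):
        with resources.as_file(_fixture_path(f"{name}.tsv")) as p:
            return PresenceMatrix.from_tsv(p)
    if name == "human_keratin_locus":
        with resources.as_file(_fixture_path("human_keratin_locus.tsv")) as p:
            return read_locus_map(p, format="tsv")
    if name == "tetrapod_locus_maps":
        maps = {}
        root = _fixture_path("locus_maps")
        for entry in sorted(root.iterdir(), key=lambda e: e.name):
            if entry.name.endswith(".tsv"):
                with resources.as_file(entry) as p:
                    m = read_locus_map(p, format="tsv")
                maps[m.species] = m
        return maps
    if name == "pairing_rules":
        with resources.as_file(_fixture_path("pairing_rules.tsv")) as p:
            return PairingRules.from_tsv(p)
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
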