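# dollotrace

Comparative-genomics inference of gene gain and loss histories, built
around the evolutionary fate of the keratin gene *KRT24* in amniotes.
`dollotrace` is for molecular evolution researchers who have per-species
gene maps, coding sequences and a timed species tree, and want to turn
them into an auditable chain of inferences:

1. **Positional orthology by shared synteny** (`dollotrace.locus`) —
   genes are matched between species not by sequence similarity but by
   their position between conserved flanking anchor genes (for *KRT24*:
   the window bordered by *KRT222* and *KRT12* in the type I keratin
   cluster). Fragmented assemblies yield an explicit
   `WINDOW_INCOMPLETE`/UNKNOWN call, never a fabricated absence.
2. **ORF integrity and pseudogene classification** (`dollotrace.orf`) —
   premature stop codons, frameshifting indels (detected by global
   alignment against an intact reference ORF), start-codon loss;
   nonsense-mediated decay (NMD) is predicted for stops upstream of the
   last exon–exon junction, and stops that truncate the central
   intermediate-filament (rod) domain mark the product nonfunctional.
3. **Dollo parsimony on a timed tree** (`dollotrace.dollo`) — a gene
   arises once and can only be lost. For each presence/absence column
   the unique minimum-loss history places the gain above the MRCA of all
   gene-bearing species and one loss on each highest edge whose subtree
   contains only gene-lacking species. Events are dated to branch
   intervals `[age(parent), age(child)]` in million years. A generalized
   Sankoff dynamic program with explicit gain/loss costs serves as a
   cross-check.
4. **Loss-pattern co-evolution and heterodimers**
   (`dollotrace.coevolution`) — strict co-evolution (identical loss
   branches), a Jaccard concordance statistic with a permutation null,
   and putative type II:type I keratin heterodimer tables per species
   (functional keratin filaments require a type I:type II pair).
5. **qPCR relative quantification** (`dollotrace.qpcr`) — the
   amplification-efficiency model `ratio = E_t^(−Ct_t) / E_r^(−Ct_r)`
   (the ΔCt model at E = 2), max-normalization to 10 arbitrary units,
   and an exact two-tailed Mann-Whitney U test for group comparisons.
6. **Synthetic data with ground truth** (`dollotrace.simulate`) — a
   Dollo loss process on the tree (per-edge loss probability
   `1 − exp(−λt)`), CDS mutators that plant known lesions, locus-map
   edit scripts, and Ct tables with Gaussian cycle noise; plus packaged
   fixtures transcribing the published species states.

## Worked example

Reconstruct the loss history of *KRT24* across mammals from the packaged
fixtures:

```python
import dollotrace as dt

tree = dt.load_fixture("mammal_tree")          # timed tree, 22 species
states = dt.load_fixture("krt24_states")       # functional states, 15 species

events = dt.dollo_reconstruct(
    states.column("KRT24"), tree, gene="KRT24",
    ancestral_at_root=True,   # the gene predates mammals
)
print(sorted(events.loss_branches))
print(dt.count_independent_losses(events, tree))
print(events.intervals)
```

prints

```
['Camelus', 'Cetacea', 'Otaroidea']
3
{'Camelus': (25.0, 5.0), 'Cetacea': (54.0, 32.0), 'Otaroidea': (24.0, 19.0)}
```

i.e. three independent losses of *KRT24*: on the stem branch of
cetaceans (after the split from the hippopotamus lineage, between ~54
and ~32 million years ago), on the stem of Otaroidea (eared seals plus
walrus, ~24–19 MY), and on the stem of the genus *Camelus* (after the
split from the alpaca, ~25–5 MY). The same computation is available from
the shell:

```bash
dollotrace events --tree mammal_tree.nwk --matrix krt24_states.tsv \
    --ancestral-at-root KRT24 --out events/
```

## Layout

```
src/dollotrace/     locus, orf, trees, dollo, coevolution, qpcr,
                    simulate, cli; packaged fixtures under fixtures/
tests/              unit, property and end-to-end suites
docs/methods.md     models, assumptions, numerical choices, limitations
scripts/            acceptance.py
```
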