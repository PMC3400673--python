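# barcodegap

DNA-barcode species delimitation and molecular dating for COI surveys, built
around the analysis style used for radiations such as the Indo-Australian
rainbowfishes: many nominal species, strong geographic structure, and a mix
of full-length (≈1800 bp) and 5′-fragment (≈650 bp) barcode products.

It is aimed at researchers who have a FASTA of aligned COI barcodes and a
specimen table (species, genus, clade, locality, region) and want the
standard battery of barcode analytics with explicit, testable conventions:

* **K2P distances** under pairwise deletion. For transition proportion *P*
  (A↔G, C↔T) and transversion proportion *Q*,

  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

  with a minimum-overlap floor so 650/1800-bp mixtures never yield distances
  from tiny overlaps.
* **Neighbour-joining trees** (Saitou–Nei) with deterministic tie-breaking,
  midpoint rooting, monophyly queries and patristic distances. NJ is exact on
  additive matrices — the property the tests enforce.
* **Barcode-gap summaries**: within-species / within-genus-among-species /
  within-family / within-order distance ladders, the congeneric-vs-conspecific
  fold ratio, nearest-neighbour distances binned at 0.1 / 1.0 / 2.7 %, and
  per-species diagnoses (captured, mixed via haplotype sharing or
  non-exclusivity, or private-cluster candidate new lineage).
* **Π<sub>ST</sub> phylogenetic community structure**: with δ<sub>within</sub>
  the mean phylogenetic distance between distinct lineages co-occurring in a
  region and δ<sub>among</sub> the mean distance between lineages of different
  regions, Π<sub>ST</sub> = 1 − δ<sub>within</sub>/δ<sub>among</sub> (> 0 for
  clustering), tested by permuting lineage identities.
* **Divergence dating**: ages t = d/r under literature substitution-rate
  hypotheses (minimum 0.005, fish 0.012, vertebrate 0.02 pairwise
  substitutions per site per Myr) and geology-based rate calibration from
  dated uplift events (Lengguru arch 8–11 Myr, Mok ridge 1.65–3.4 Myr).
* **A ground-truth simulator** evolving sequences under the K2P process along
  a clock-like clade/species/individual hierarchy, with planted cryptic
  lineages and phylogenetically clustered regions, so every stage is testable
  without downloads.

## Worked example

Run the whole pipeline on the built-in synthetic cohort (275 specimens:
4 clades × 13 species × 5 individuals + 15 planted singleton lineages,
650-bp barcodes, 7 regions):

```python
from barcodegap import RunConfig, run

bundle = run(RunConfig(scenario_seed=1, n_perm=999, seed=1, outdir="demo_out"))
print(bundle.results)
```

```
{'fold_ratio': 9.115868896561095,
 'n_new_lineage_candidates': 15,
 'pi_st': 0.5307262698873237,
 'pi_st_p': 0.001,
 'dating_pairs': 10}
```

Reading the numbers: congeneric species diverge ~9× more than conspecific
individuals in this cohort (the level table in `demo_out/table_levels.csv`
shows within-species mean 0.61 % vs within-genus-among-species 5.53 %); all
15 planted isolated lineages are flagged as private-cluster candidates;
regions are strongly phylogenetically clustered (Π<sub>ST</sub> = 0.53, the
upper-tail permutation p-value is 0.001 at 999 permutations). The dating
table (`demo_out/dating.csv`) gives, e.g., clades I vs II at mean K2P
divergence 0.136, hence 27.2 Myr under the minimum rate and 11.3 Myr under
the fish rate, and a Lengguru-calibrated rate interval of 0.012–0.017
substitutions/Myr containing the fish rate.

The same stages are available as library calls (`distance_matrix`,
`neighbor_joining`, `midpoint_root`, `level_partition`, `nearest_neighbors`,
`diagnose_species`, `pi_st_test`, `clade_stats`, `dating_report`) and as CLI
subcommands:

```sh
barcodegap simulate --seed 1 --output sim/
barcodegap distances --fasta sim/sequences.fasta --metadata sim/metadata.tsv --output d.csv
barcodegap run --scenario-seed 1 --n-perm 999 --seed 1 --output demo_out
```

## Layout

```
src/barcodegap/
  dataio.py     FASTA/TSV ingestion, coding-sequence validation, dataset join
  k2p.py        pairwise K2P distances, distance matrix, missing/saturation
  njtree.py     neighbour joining, midpoint rooting, tree queries
  summaries.py  level ladders, fold ratio, nearest neighbours, diagnoses
  community.py  Pi_ST and its permutation test
  dating.py     ages under rate hypotheses, geology-based calibration
  simulate.py   ground-truth simulator (K2P process on a clock-like tree)
  pipeline.py   end-to-end orchestration and report bundle
  cli.py        thin click CLI
docs/methods.md   model, conventions and design notes
```
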