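# invanet

Analysis pipeline for paired invaded/native rhizosphere soil microbiome
surveys: community diversity and ordination statistics, absolute
quantification of element-cycling (CNPS) genes from high-throughput qPCR
chips, co-occurrence / functional molecular ecological network (fMEN)
construction with keystone-taxon identification, driver-importance analysis,
and inverse-distance-weighted spatial interpolation.

The package is aimed at soil-microbiome researchers studying how plant
invasion (e.g. *Amaranthus palmeri* encroaching on native vegetation)
restructures bacterial communities and their functional potential. Field
studies of this kind sample adjacent invaded/native pairs at many sites,
sequence 16S amplicons to an OTU table, and profile carbon-, nitrogen-,
phosphorus- and sulfur-cycle genes on a qPCR chip (71 functional assays plus
a 16S reference). Because such datasets are expensive and rarely
redistributable, the package ships a first-class synthetic-data generator
that emulates the paired design and plants known structure — keystone OTUs,
group effects, spatial gradients — so every stage of the pipeline is
testable against ground truth.

## Methods at a glance

* **Alpha diversity** — richness S, bias-corrected Chao1
  `S + F₁(F₁−1)/(2(F₂+1))`, ACE (rare cutoff 10), Shannon `H = −Σ pᵢ ln pᵢ`,
  Gini–Simpson `1 − Σ pᵢ²`, computed on rarefied counts (sampling without
  replacement to a common depth).
* **Beta diversity** — Bray–Curtis `d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`, principal
  coordinates (Gower-centered −½d², eigendecomposition, axes scaled by √λ),
  and ANOSIM: with all M = n(n−1)/2 distances ranked,
  `R = (r̄_between − r̄_within)/(M/2)`, p from seeded label permutations.
* **qPCR quantification** — a cycle threshold (CT) of 31 is the detection
  limit; relative copies `N₀ = E^(31−CT)` with assay efficiency E (assays
  with E outside [1.8, 2.2] are discarded); absolute copies scale relative
  copies by each sample's absolute 16S copy number.
* **Networks** — features present in >80% of samples enter an all-pairs
  Spearman correlation; p-values are BH-FDR adjusted over the network's pair
  family; an edge requires |ρ| > 0.6 (OTU–gene fMEN preset; 0.8 for the
  gene–gene preset) and q < 0.05. Topology reports degree, clustering,
  transitivity, greedy modularity, distances and signed edge counts.
  Keystone taxa are the top-5 degree OTU nodes.
* **Drivers** — permutation importance (%IncMSE from an out-of-bag-evaluated
  bagged regression forest) and LMG averaged-over-orderings R² decomposition,
  both with response-permutation significance; ln–ln keystone–gene
  regressions; redundancy analysis of edaphic variables with a permutation
  F-test.
* **Spatial** — exact inverse-distance-weighted interpolation
  (`w ∝ d^−power`) over the study bounding box, plus north/south
  Kruskal–Wallis contrasts per gene category.

## Worked example

```python
from invanet import community, network, qmec
from invanet.io import FeatureTable
from invanet.synth import SynthConfig, generate_dataset

ds, truth = generate_dataset(SynthConfig(seed=1))          # 22 paired sites
rarefied = community.rarefy(ds.otus, seed=1)
dm = community.bray_curtis(rarefied)
print(community.anosim(dm, ds.metadata.groups, n_permutations=999, seed=1))

quant = qmec.quantify(ds.ct, ds.panel, ds.abs_16s)          # CT → copies/g
genes = FeatureTable(quant.absolute, kind="gene", units="copies_per_gram")
ap = ds.metadata.groups.index[ds.metadata.groups == "AP"]
net = network.build_network(ds.otus.subset_samples(ap), genes.subset_samples(ap))
print(network.keystone_table(net, ds.taxonomy).iloc[:, :4])
print("planted:", truth.keystones["AP"])
```

prints

```
ANOSIM R = 0.497, p = 0.001 (999 permutations)
         degree  mean_abundance    domain          phylum
otu_id
OTU_153      75        0.009240  Bacteria  Actinobacteria
OTU_205      73        0.058423  Bacteria   Bacteroidetes
OTU_300      68        0.023774  Bacteria  Proteobacteria
OTU_53       40        0.020707  Bacteria  Proteobacteria
OTU_61       32        0.020752  Bacteria  Planctomycetes
planted: ['OTU_53', 'OTU_61', 'OTU_153', 'OTU_205', 'OTU_300']
```

The ANOSIM R of 0.50 (p = 0.001) says invaded and native communities are
clearly separated in Bray–Curtis space on this dataset — the generator's
group effect at work. The keystone table is the top-5 degree OTU nodes of
the invaded-group fMEN with their lineages; here all five planted keystones
are recovered.

The same pipeline runs from the shell:

```bash
invanet simulate --seed 1 --out data/
invanet run --config cfg.yaml --seed 1 --out results/
```

`invanet run` executes simulate/ingest → quantification → diversity →
networks (both presets) → keystones → drivers → spatial and writes
`report.json` with every statistic plus the seeds and parameters that
produced them; identical config and seed give byte-identical reports.

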