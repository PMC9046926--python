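# degvenn

**Group-specific differential expression, done right — and a working model
of how it goes wrong.**

A recurring pattern in transcriptomics: two patient groups, each with
treated and control samples; differential expression is run *separately*
per group; genes significant in one group but not the other are declared
"group-specific" (the non-overlapping parts of the Venn diagram) and fed
into gene-set enrichment to find "pathways regulated in only this group".
This reasoning is invalid — the difference between significant and
non-significant is not itself statistically significant — and, worse, the
enrichment results it produces look biologically sensible, because the
falsely "specific" genes are mostly genuine treatment responders that one
of the two underpowered tests happened to miss (false negatives).

The statistically correct question is the **group × condition
interaction**: in the NB-GLM

log μ<sub>gj</sub> = log s<sub>j</sub> + β₀ + β<sub>G</sub>·group + β<sub>T</sub>·condition + β<sub>G×T</sub>·group·condition,

the contrast β<sub>G×T</sub> (difference of the two treatment effects).

`degvenn` packages the whole demonstration:

* `degvenn.simulate` — NB count simulator for the 2×2 design with known
  truth (shared effects, optional true interaction, dispersion trend,
  size factors) and synthetic gene-set catalogs in which treatment-response
  genes are concentrated.
* `degvenn.diffexp` — a self-contained NB-GLM DE engine: median-of-ratios
  size factors, Cox–Reid profile-likelihood dispersions, batched IRLS,
  Wald contrasts (`trt_in_G1`, `trt_in_G2`, `interaction`), BH adjustment,
  strict DEG calling, Venn partitioning.
* `degvenn.enrichment` — hypergeometric overrepresentation analysis,
  the rank-based CERNO test (−2Σln(rᵢ/N), χ² with 2|S| df), and the signed
  disco concordance score.
* `degvenn.power` — two-sample t-test power / required-n from the
  noncentral t distribution.
* `degvenn.harness` — replicated incorrect-vs-correct comparisons and the
  LFC-threshold × sample-size grid; paired-LFC scatter export as the
  recommended alternative to Venn diagrams.
* `degvenn.io` / `degvenn.cli` — TSV/GMT formats, manifests, and the
  `degvenn` command (`simulate`, `diffexp`, `enrich`, `study`, `power`).

## Worked example

One replicate of the full study at the default world — 5000 genes, 20
samples per group×condition cell, 10% of genes with a treatment effect
**shared identically by both groups**, zero true interaction:

```python
import degvenn as dv

cfg = dv.SimulationConfig(seed=11)
s = dv.run_replicate(cfg)
print(s.degs_g1, s.degs_g2, s.degs_both, s.degs_only_g1, s.degs_only_g2)
print(s.ora_sig_only_g1, s.ora_sig_only_g2, s.interaction_degs, s.cerno_sig_sets)
print(round(s.fn_composition, 2))
```

prints

```
158 152 79 79 73
31 25 1 0
0.84
```

Read: each group shows ~150 DEGs but only 79 are shared — the Venn diagram
suggests mostly "group-specific" responses. The naive pipeline then finds
31 + 25 = 56 significantly enriched gene sets on the "specific" lists, all
56 of them response-labelled sets (biologically plausible-looking!). Yet
the correct interaction analysis finds essentially nothing (1 gene at
FDR < 0.05 out of 5000; CERNO on the interaction ranking: 0 sets) — as it
should, since no gene truly differs between groups. The truth table shows
84% of the "specific" DEGs are genes truly DE in *both* groups: false
negatives, not biology.

The same from the shell:

```sh
degvenn study --replicates 20 --seed 1 --out results/study
degvenn power --d 0.8 --alpha 0.05 --power 0.8 --json
```

The power subcommand prints `"n_per_group": 26` — even a large effect
(Cohen's d = 0.8) needs 26 samples per group for 80% power, i.e. a 20%
false-negative rate at best; small effects (d = 0.2) need 394. That
arithmetic is the engine of the artifact.

## Acceptance script

`scripts/acceptance.py` recomputes the package's quantitative reference
values from scratch — the minimal per-group sample sizes at which the
two-sided two-sample t-test reaches 80% power at α = 0.05 for d = 0.8 and
d = 0.2, evaluated from the noncentral t distribution:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The scientific background, simulator assumptions, numerical choices and
known limitations are documented in [docs/methods.md](docs/methods.md).
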