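# actd — anti-cancer target discovery with side-effect grading

`actd` screens candidate drug targets — enzymes and antimetabolites — in a
*pair* of constraint-based metabolic models: one reconstructed for cancer
(CA) tissue and one for its healthy (HT) counterpart.  Most computational
target screens stop at synthetic lethality in the cancer model; `actd`
additionally asks what the same perturbation does to the healthy cell, and
scores every candidate on three axes at once:

* **cancer-cell mortality** — how far the treated CA cell's growth and ATP
  production fall,
* **healthy-cell viability** — whether the perturbed HT cell keeps
  producing ATP without proliferating,
* **metabolic deviation** — how far the perturbed HT cell's flux pattern
  and metabolite flow rates drift from the healthy baseline (a proxy for
  side effects).

It is aimed at systems-biology and computational drug-discovery groups
working with genome-scale metabolic models (SBML/FBC, or the package's
TSV/JSON dialects).

## The model

Each model is flux-split into nonnegative forward/backward variables
`v_f, v_b ≥ 0` with net flux `v = v_f − v_b`.  For every candidate
perturbation two nested problems are solved per model:

1. **FBA (LP)** — maximize `v_biomass` (CA) or `v_ATP` (HT) subject to
   steady state `N(v_f − v_b) = 0` and the regulated bounds;
2. **UFD (QP)** — minimize `Σ_k c_k (v_f,k² + v_b,k²)` over internal
   reactions with the FBA optimum as a floor.  The weights
   `c_k ∈ {¼, ½, ¾, 1}` come from RNA-seq-derived reaction confidence
   (high → ¼ … other → 1), so well-supported reactions may carry more
   flux.  The unique QP solution is the representative flux pattern.

Candidate regulation follows the gene–protein-reaction (GPR) logic:
knocking out an enzyme zeroes only the reactions it exclusively
catalyses; a reaction still covered by another isozyme is held within
`±ε` (default 3%) of its basal template flux.  Up-/down-regulation moves
bounds by the convex combination `(1−δ)·basal + δ·bound` with the
modulation `δ ∈ [0,1]` a decision variable.  Antimetabolites are modeled
by blocking every producing direction of the target metabolite.

Flux values become membership grades `η ∈ [0,1]` through linear fuzzy
membership functions, aggregated pairwise with the **mean–min operator**
`(mean + min)/2`, which discriminates grade vectors of equal mean.  The
overall metabolic-deviation grade is the mean–min of four
similarity/dissimilarity grades of the perturbed HT state against the HT
and CA templates, and the final hierarchical objective is

```
η_D = (η_TR + min{η_TR, η_CV, η_MD}) / 2
```

so cancer mortality (`η_TR`) is the first priority.  One-target screens
enumerate every feasible enzyme; two-target screens search cross-group
pairs (`|G1|·|G2|` combinations instead of `C(n,2)`) with a **nested
hybrid differential evolution** (NHDE) whose fitness evaluation runs the
full inner pipeline, memoized over target sets.

## Worked example

The package ships a seeded toy CA/HT generator with planted phenotypes
(a CA-essential/HT-dispensable nucleotide-synthesis enzyme, a
shared-essential glycolytic enzyme, an isozyme pair that is only jointly
lethal):

```bash
actd make-toy --seed 3 --out-dir toy
printf 'biomass_rxn_id: r_bio\natp_rxn_id: DM_atp\n' > toy/cfg.yaml
actd one-target --ca-model toy/toy_CA_reactions.tsv \
    --ht-model toy/toy_HT_reactions.tsv --config toy/cfg.yaml --out toy/one.tsv
head -5 toy/one.tsv
```

prints

```
targets      modes     delta  eta_tr    eta_cv    eta_md    eta_d     status_ca  status_ht
Gcad         knockout  1      0.250000  1.000000  0.802459  0.250000  optimal    optimal
Grpia        knockout  1      0.250000  1.000000  0.802459  0.250000  optimal    optimal
Gglyc1       knockout  1      0.250000  0.281000  0.670602  0.250000  optimal    optimal
Gtca1+Gtca2  knockout  1      0.016249  0.590999  0.742227  0.016249  optimal    optimal
```

Reading the rows: knocking out `Gcad` (nucleotide synthesis) stops
cancer growth completely (`η_TR = 0.25`: the growth grade saturates at 1
while the ATP-demand grade stays 0 because maintenance ATP is still
made), leaves the healthy cell untouched (`η_CV = 1`) and barely
perturbs its metabolism (`η_MD = 0.80`).  The shared-essential `Gglyc1`
kills the cancer cell equally well but collapses healthy ATP production
(`η_CV = 0.28`) with a larger metabolic footprint (`η_MD = 0.67`) — a
high-side-effect target.  Rows are ranked by `(η_D, η_MD)`, so the
low-side-effect kill comes first.

The same screens are available from Python (`actd.build_context`,
`actd.enumerate_one_target`, `actd.pair_search`,
`actd.screen_antimetabolites`) and for metabolite targets
(`actd antimetabolite`), e.g. blocking orotate synthesis reproduces the
grades of the `Gcad` knockout.

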