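# phenorecon

Phenotype-driven refinement of genome-scale metabolic models, built around
the workflow of systematic chromosome-interval deletion studies: predict the
viability of multi-gene deletion strains on defined media with flux balance
analysis (FBA), reconcile the model against the observed growth phenotypes
through twelve typed error classes, and propose rescue metabolites for
strains predicted unviable.

It is aimed at people curating constraint-based models against knockout
phenotype panels — the situation where a strain collection (here, contiguous
chromosome intervals delimited by preserved genes) has been scored
viable/slow/unviable on several media, and each disagreement with the model
is a lead toward a concrete model or media fix.

## The model

FBA predicts growth as the optimum of a linear program over steady-state
fluxes *v*:

```
maximize    c·v            (biomass flux)
subject to  S·v = 0        (mass balance around every metabolite)
            lb ≤ v ≤ ub    (reversibility / directionality, media uptakes)
```

Media enter as lower bounds on exchange reactions (uptake is negative
exchange flux; unlisted compounds are closed). A deletion strain is
simulated by forcing zero flux through every reaction whose gene–protein–
reaction (GPR) boolean rule evaluates false with the deleted genes absent:
`and` encodes complexes, `or` isozymes. A strain is called viable when the
biomass optimum exceeds ε = 1e−6.

Prediction errors are either false positives (predicted viable, observed
unviable) or false negatives (the reverse), and each direction admits six
correction classes: biomass-composition edits, GPR adjustments, isozyme
removals/additions, reaction removals/additions (gapfilling), reversibility
changes, and media-compound changes. Reconciliation is a greedy loop:
propose candidate edits for every failing (strain, media) pair — each must
flip its prompting prediction in isolation — evaluate every candidate's
global effect (predictions corrected minus predictions broken), accept the
best strictly net-positive edit, re-simulate, repeat. Accuracy therefore
increases monotonically and the loop terminates; conflicts that cannot be
fixed without breaking something else stay in the residual list, flagging
likely regulatory (non-metabolic) effects.

Because real study data is rarely at hand, the package ships a first-class
synthetic-data generator: a gene-ordered toy genome whose
preserved genes delimit deletion intervals, a ground-truth network of linear
biosynthetic pathways with isozymes, transporters and interconversions, four
media (rich, defined rich, and two minimal media differing in nitrogen
source), phenotypes that are the truth network's own FBA verdicts, and a
planter that corrupts the model with the inverse of any error class while
recording the true fix.

## Worked example

```python
import phenorecon as pr
from phenorecon.synthetic_data import PlantSpec, plant_errors, candidate_db_from_truth
from phenorecon.reconciliation import reconcile_greedy

bundle = pr.make_truth_bundle(seed=42)          # genome, network, media, phenotypes
corrupted, media, planted = plant_errors(
    bundle, PlantSpec({"FN_reaction_add": 1, "FP_media_remove": 1}, seed=3)
)
matrix = pr.batch_predict(corrupted, bundle.strain_defs(), list(media.values()))
print(pr.score_predictions(matrix, bundle.phenotypes).to_frame())

db = candidate_db_from_truth(bundle.truth_model, corrupted)
refined, rmedia, ledger = reconcile_greedy(
    corrupted, media, db, bundle.strain_defs(), bundle.phenotypes
)
for e in ledger.entries:
    print(e.hypothesis.id, e.delta.net, e.accuracy_before, e.accuracy_after)
```

The corrupted model (one deleted nitrogen-assimilation reaction, one
spurious medium compound) scores:

```
       media phenotype   n  correct  percent
        mm_A         +   6        5     83.3
        mm_A         -   5        3     60.0
     Overall         +  29       26     89.7
     Overall         -  15       13     86.7
     Overall       all  44       39     88.6
```

The accuracy table splits observed-viable (`+`) from observed-unviable (`−`)
strains per medium, because the two error directions behave very
differently. Reconciliation then recovers exactly the planted corruptions:

```
accepted FN_reaction_add:reaction_ids=ASSIM_A            net=3  acc 88.6% -> 95.5%
accepted FP_media_remove:compound=amB_e,media=mm_A       net=2  acc 95.5% -> 100.0%
```

Each line is one accepted edit with its net corrected-minus-broken count and
the overall accuracy before/after; the refined model reproduces every
observed phenotype.

A command-line interface wraps the same pipeline
(`phenorecon simulate | predict | reconcile | rescue`); each subcommand
writes TSV/SBML/JSON artifacts and is byte-reproducible for a fixed seed.

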