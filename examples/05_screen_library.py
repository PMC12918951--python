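"""Virtually screen an external library with a trained model.

The library is standardized, deduplicated against the training set, scored,
and pushed through the filter cascade: probability > 0.8, zero Rule-of-Five
violations, zero PAINS alerts, at most one Brenk alert, plus the annotation
criteria (blood-brain-barrier permeability, no prior TDP-43 testing).
Novelty is the maximum Tanimoto similarity to the training actives.
"""

import numpy as np
import pandas as pd

from tdpred.chemio import deduplicate
from tdpred.dmpnn import MPNNConfig
from tdpred.featurize import fingerprint_matrix
from tdpred.fingerprints import compute_ecfp
from tdpred.model import PipelineOptions, fit_final, nested_cv
from tdpred.screen import filter_cascade, novelty, predict_library
from tdpred.split import add_outer_folds, butina_cluster, cluster_train_test_split
from tdpred.synthdata import GeneratorConfig, generate_dataset, generate_screening_library

# train at desk scale (see example 03 for the stages)
records = generate_dataset(GeneratorConfig(n_compounds=400, seed=11))
labels = np.array([r.label for r in records])
ids = [r.id for r in records]
assignment = butina_cluster(list(fingerprint_matrix(records).values), 0.4)
plan = cluster_train_test_split(assignment, labels, ids, seed=11)
plan = add_outer_folds(plan, assignment, dict(zip(ids, labels.tolist())), ids, k=2, seed=11)
options = PipelineOptions(families=("GNN", "DESCRIPTOR", "TARGET"), budget=120,
                          n_iter=2, inner_k=2, seed=11,
                          mpnn=MPNNConfig(depth=2, hidden=48, ffn_hidden=48, max_epochs=8))
cluster_of_id = {rid: assignment.cluster_of[i] for i, rid in enumerate(ids)}
_reports, configs = nested_cv(records, plan, cluster_of_id, options)
bundle, _ = fit_final(records, plan, configs, options)

# screening library: same chemistry, no labels; deduplicated against training
library = generate_screening_library(GeneratorConfig(n_compounds=150, seed=42))
by_id = {r.id: r for r in records}
library = deduplicate(library, reference=[by_id[i] for i in plan.train_ids])
probs, scored, rejects = predict_library(bundle, library)
print(f"scored {len(scored)} library compounds ({len(rejects)} rejects)")

# annotation columns stand in for external ADME/literature curation
ann = pd.DataFrame({"bbb_permeable": True, "prior_tdp43": False},
                   index=[r.id for r in scored])
report = filter_cascade(probs, scored, annotations=ann)
print("cascade survivors per stage:", report.stage_counts)

active_fps = np.array([compute_ecfp(r.smiles_std) for r in records if r.label == 1])
for rid in report.survivors()[:5]:
    row = report.table.set_index("id").loc[rid]
    nov = novelty(compute_ecfp(row["smiles"]), active_fps)
    print(f"  hit {rid}: probability {row['probability']:.2f}, "
          f"max Tanimoto to training actives {nov:.2f}")
# Low max-Tanimoto hits are the interesting ones: active chemistry the
# training set does not already contain.
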