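"""Interpret a trained hybrid model.

Exact tree-conditional Shapley values rank the features driving predictions;
the target-descriptor correlation table checks that annotations and chemistry
carry complementary information; and Monte-Carlo tree search extracts the
substructure of an active molecule that keeps the encoder's predicted
activity high (on this synthetic data it should recover the planted
quinoline motif).
"""

import numpy as np
from rdkit import Chem

from tdpred.dmpnn import MPNNConfig
from tdpred.featurize import fingerprint_matrix
from tdpred.interpret import (mcts_rationale, rank_features,
                              shapley_attributions,
                              target_descriptor_correlation)
from tdpred.model import PipelineOptions, fit_final, nested_cv
from tdpred.split import add_outer_folds, butina_cluster, cluster_train_test_split
from tdpred.synthdata import DEFAULT_MOTIF_SMARTS, GeneratorConfig, generate_dataset, has_motif

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

by_id = {r.id: r for r in records}
test_records = [by_id[i] for i in plan.test_ids]
feats = bundle.mask.apply(bundle.pipeline.transform(test_records))

attr = shapley_attributions(bundle.model, feats)
print("local accuracy check:",
      np.abs(attr.base_value + attr.values.sum(1)
             - [bundle.model.estimator.predict(feats.values[i:i+1],
                output_margin=True)[0] for i in range(len(test_records))]).max())
print("\ntop 10 features by mean |Shapley value|:")
print(rank_features(attr, top_k=10).to_string(index=False))

from tdpred.featurize import Family
corr = target_descriptor_correlation(
    feats, target_names=feats.family_columns(Family.TARGET)[:3],
    descriptor_names=feats.family_columns(Family.DESCRIPTOR)[:3])
print("\ntarget-descriptor correlations (weak = complementary information):")
print(corr.to_string(index=False))

active = next(r for r in test_records if r.label == 1 and has_motif(r))
rats = mcts_rationale(bundle.pipeline.encoder, active.smiles_std,
                      parent_id=active.id, n_rollouts=300, seed=0, top_k=1)
motif = Chem.MolFromSmarts(DEFAULT_MOTIF_SMARTS)
frag = Chem.MolFromSmiles(rats[0].smiles)
print(f"\nrationale for {active.id} ({active.smiles_std}):")
print(f"  substructure {rats[0].smiles}  score {rats[0].score:.3f}")
print(f"  contains planted motif: {frag.HasSubstructMatch(motif)}")
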