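"""Ground-truth recovery benchmarks on simulated campaigns.

Each function runs one pipeline capability end to end on synthetic campaigns
with known truth and returns the recovery metrics: enrichment ranking of
planted binders, classifier recovery of sequence-coupled labels, exactness
of the liability screen, and the two-group epitope-binning reconstruction.
They are used by the test suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import balanced_accuracy_score

from . import assays, convnet, enrichment, knn, liabilities, synthetic


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def enrichment_recovery(
    n_clones: int = 2000,
    n_seeds: int = 20,
    seed: int = 0,
    min_round3_reads: int = 10,
) -> dict:
    """Planted-binder recovery by round-3-to-4 enrichment ranking.

    Per campaign: does the top enrichment-ranked clonotype carry a true
    binder CDR3, and how well does per-clone enrichment rank affinity
    (Spearman of -log10 K_D vs log2 enrichment over clones with at least
    ``min_round3_reads`` round-3 reads)?
    """
    top_hits, rhos = [], []
    for s in _subseeds(seed, n_seeds):
        camp = synthetic.simulate_campaign(n_clones=n_clones, seed=s)
        variants = enrichment.campaign_variants(camp, rounds=(3, 4))
        cts, _ = enrichment.assign_clonotypes(variants)
        table = enrichment.build_enrichment_table(cts, 3, 4)
        cands = enrichment.select_enrichment_candidates(
            table, cts, n_top_clonotypes=1, min_count_a=min_round3_reads)
        top_key = next(ct.key for ct in cts
                       if ct.clonotype_id == cands[0].clonotype_id)
        top_hits.append(top_key in camp.design.binder_cdr3_aa)
        t3 = sum(camp.round_counts[3].values())
        t4 = sum(camp.round_counts[4].values())
        pseudo = 1.0 / np.sqrt(t3 * t4)
        neg_log_kd, scores = [], []
        for clone in camp.clones:
            n3 = camp.round_counts[3][clone.clone_id]
            if n3 < min_round3_reads:
                continue
            score = enrichment.compute_enrichment(
                n3 / t3, camp.round_counts[4][clone.clone_id] / t4, pseudo)
            neg_log_kd.append(-np.log10(clone.kd))
            scores.append(score)
        rhos.append(float(spearmanr(neg_log_kd, scores).statistic))
    return {
        "top_clonotype_binder_rate": float(np.mean(top_hits)),
        "spearman_median": float(np.median(rhos)),
        "spearman_all": rhos,
        "n_seeds": n_seeds,
        "n_clones": n_clones,
    }


def _campaign_split(n_clones: int, seed: int, n_train: int,
                    label_noise: float):
    """Simulate a campaign and split clones into noisy-labelled training
    (emulating binding-assay readout) and clean-truth held-out sets."""
    camp = synthetic.simulate_campaign(n_clones=n_clones, seed=seed)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_clones)
    train = [camp.clones[i] for i in idx[:n_train]]
    test = [camp.clones[i] for i in idx[n_train:]]
    spr = []
    for clone in train:
        label = bool(clone.is_binder)
        if rng.random() < label_noise:
            label = not label
        spr.append((clone.aa_sequence, label))
    training = knn.build_training_set(spr_labels=spr, seed=seed)
    y_test = np.array([int(c.is_binder) for c in test])
    return training, [c.aa_sequence for c in test], y_test


def knn_recovery(n_clones: int = 2000, n_seeds: int = 3, seed: int = 0,
                 n_train: int = 1200, label_noise: float = 0.03) -> dict:
    """Held-out balanced accuracy of the tuned KNN workflow (seed median)."""
    accs = []
    for s in _subseeds(seed, n_seeds):
        training, X_test, y_test = _campaign_split(n_clones, s, n_train,
                                                   label_noise)
        model = knn.tune_knn(training, seed=s)
        accs.append(float(balanced_accuracy_score(y_test,
                                                  model.predict(X_test))))
    return {"balanced_accuracy_median": float(np.median(accs)),
            "all": accs, "n_clones": n_clones, "n_seeds": n_seeds}


def conv_recovery(n_clones: int = 2000, n_seeds: int = 3, seed: int = 0,
                  n_train: int = 1200, label_noise: float = 0.03,
                  epochs: int = 10) -> dict:
    """Held-out F1 of the convolutional workflow (seed median)."""
    f1s = []
    for s in _subseeds(seed, n_seeds):
        training, X_test, y_test = _campaign_split(n_clones, s, n_train,
                                                   label_noise)
        model = convnet.train_conv_classifier(training, epochs=epochs, seed=s)
        prob = model.predict_proba(X_test)
        f1s.append(knn.fbeta_from_predictions(y_test,
                                              (prob >= 0.5).astype(int), 1.0))
    return {"f1_median": float(np.median(f1s)), "all": f1s,
            "n_clones": n_clones, "n_seeds": n_seeds}


def permutation_null(n: int = 120, n_perms: int = 20, seed: int = 0) -> dict:
    """Tuned F-beta under label permutation vs the prevalence baseline.

    With labels shuffled, a classifier's precision collapses to class
    prevalence; the mean tuned F-beta should sit near it.
    """
    rng = np.random.default_rng(seed)
    alphabet_pos, alphabet_neg = list("KRED"), list("LVIA")
    seqs, labels = [], []
    for i in range(n):
        alpha = alphabet_pos if i < n // 2 else alphabet_neg
        seqs.append("".join(rng.choice(alpha, size=30)))
        labels.append(i < n // 2)
    labels = np.array(labels)
    scores = []
    for _ in range(n_perms):
        perm = rng.permutation(labels)
        training = knn.build_training_set(
            spr_labels=[(s, bool(l)) for s, l in zip(seqs, perm)])
        model = knn.tune_knn(training,
                             grid={"pca_components": (2,), "k_neighbors": (3,)},
                             cv_folds=3, seed=0)
        scores.append(model.best_score)
    return {"mean_permuted_fbeta": float(np.mean(scores)),
            "prevalence": float(labels.mean()), "n": n, "n_perms": n_perms}


def liability_exactness(n_clones: int = 500, liability_fraction: float = 0.2,
                        seed: int = 0) -> dict:
    """Precision/recall of the liability filter against the planted truth."""
    design = synthetic.default_library_design(
        seed=seed, liability_fraction=liability_fraction)
    camp = synthetic.generate_library(design, n_clones)
    planted = {c.clone_id for c in camp.clones if c.planted_liabilities}
    result = liabilities.filter_library([c.to_record() for c in camp.clones])
    removed = {r.read_id for r in result.removed}
    tp = len(removed & planted)
    precision = tp / len(removed) if removed else 1.0
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall,
            "n_planted": len(planted), "n_removed": len(removed),
            "n_clones": n_clones}


#: Published memberships of the two competition bins recovered for the
#: anti-DKK1 leads: the CRD2-directed pair vs the five CRD1-directed binders.
BIN1_ANTIBODIES = ("SC52-002", "control-mAb")
BIN2_ANTIBODIES = ("SC52-005", "SC52-011", "TB643-070", "TB758-030",
                   "TB758-051")


def two_bin_competition_matrix(blocked_response: float = 0.05,
                               open_response: float = 0.95) -> pd.DataFrame:
    """Relative-response matrix realizing the stated pairwise memberships:
    mutual blocking within each group, no cross-group competition."""
    names = list(BIN1_ANTIBODIES + BIN2_ANTIBODIES)
    rows = {lig: {an: (blocked_response
                       if (lig in BIN1_ANTIBODIES) == (an in BIN1_ANTIBODIES)
                       else open_response) for an in names}
            for lig in names}
    return pd.DataFrame(rows).T


def bin_reconstruction(threshold: float = 0.30) -> dict:
    """Reconstruct the two epitope bins from the membership-derived matrix."""
    blocked = assays.binarize_competition(two_bin_competition_matrix(),
                                          threshold)
    assignment = assays.assign_bins(blocked)
    sizes = sorted((len(assignment.members(b))
                    for b in set(assignment.bins.values())), reverse=True)
    return {"n_bins": assignment.n_bins, "bin_sizes": sizes,
            "assignment": assignment}
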