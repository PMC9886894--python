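"""Canonical desk-scale experiments: separable recovery and multi-task benefit.

These are the package's two headline computations, with their study
conditions fixed here so that tests, scripts and documentation all run the
same experiment.

``separable_recovery``
    Trains the joint model on a fully separable synthetic cohort (200 users,
    ~50 posts each, every post gold-labeled) and measures held-out user-level
    depression accuracy and post-level 12-way distortion accuracy.  On
    Bayes-separable text a correct implementation recovers both tasks nearly
    perfectly.

``multitask_benefit``
    The ablation experiment: does post-level distortion supervision improve
    user-level depression F1?  The conditions emulate the intended use case —
    the depression corpus carries **no** post-level labels; distortion
    supervision comes from a separate expanded-scale labeled post corpus
    (1,644 distorted + 2,000 normal); distortions are signaled only by
    marker tokens embedded in otherwise-neutral sentences
    (``marker_only_text=True``), each with many lexical surface forms
    (``marker_variants=30``) — far more than the scarce user supervision
    (40 labeled users, ~15 posts each) can cover on its own.  Both arms see
    identical inputs; the single-task ablation differs only in dropping the
    auxiliary loss (w1=0).  Compared on mean held-out F1 across seeds.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .corpus import UserRecord
from .evaluation import confusion, metrics, post_level_report
from .model import ModelConfig, MultiTaskModel
from .synthetic import GeneratorConfig, generate_corpus, generate_seed_and_pool

__all__ = ["strip_post_labels", "separable_recovery", "multitask_benefit"]


def strip_post_labels(users: Sequence[UserRecord]) -> list[UserRecord]:
    """Copies of ``users`` with all post-level distortion labels removed."""
    return [
        u.model_copy(update={
            "posts": [
                p.model_copy(update={"label": None, "label_source": "none"})
                for p in u.posts
            ]
        })
        for u in users
    ]


def separable_recovery(
    seed: int = 42,
    n_users: int = 200,
    posts_per_user: float = 50.0,
    n_train: int = 160,
    epochs: int = 25,
) -> dict:
    """Held-out accuracies of the joint model on fully separable data."""
    cfg = GeneratorConfig(n_users=n_users, posts_per_user_mean=posts_per_user,
                          signal_strength=1.0, seed=seed)
    users = generate_corpus(cfg)
    train, test = users[:n_train], users[n_train:]
    model = MultiTaskModel.fit(train, [], ModelConfig(epochs=epochs, seed=seed))
    preds = model.predict(test)
    gold_u = [u.depression_label for u in test]
    pred_u = [int(p.depression_probability >= 0.5) for p in preds]
    user_accuracy = sum(g == p for g, p in zip(gold_u, pred_u)) / len(gold_u)
    gold_c, pred_c = [], []
    for u, pr in zip(test, preds):
        posts = u.posts[-model.config.max_posts_per_user:]
        for post, pp in zip(posts, pr.post_predictions):
            gold_c.append(post.label)
            pred_c.append(pp.category)
    post_accuracy = post_level_report(gold_c, pred_c).accuracy
    return {
        "user_accuracy": user_accuracy,
        "post_accuracy": post_accuracy,
        "n_test_users": len(test),
        "n_test_posts": len(gold_c),
        "epochs_run": len(model.training_log),
    }


def _benefit_run(gen_seed: int, model_seed: int, w1: float) -> float:
    cfg = GeneratorConfig(n_users=120, posts_per_user_mean=15.0,
                          p_distortion_depressed=0.2, marker_variants=30,
                          marker_only_text=True, seed=gen_seed)
    users = generate_corpus(cfg)
    train = strip_post_labels(users[:40])
    test = users[40:]
    # both arms see identical inputs (same vocabulary, same corpora);
    # the ablation differs only in dropping the auxiliary loss term
    seed_posts = generate_seed_and_pool(
        cfg, n_seed_distorted=1644, n_seed_normal=2000, pool_size=1
    ).seed
    mc = ModelConfig(epochs=30, seed=model_seed, loss_weights=(w1, 1.0))
    model = MultiTaskModel.fit(train, seed_posts, mc)
    preds = model.predict(test)
    cm = confusion([u.depression_label for u in test],
                   [int(p.depression_probability >= 0.5) for p in preds])
    rep = metrics(cm)
    return rep.f1 if rep.f1 is not None else 0.0


def multitask_benefit(seeds: Iterable[int] = range(8), seed_offset: int = 1000) -> dict:
    """Mean held-out F1 of the joint model vs the w1=0 ablation."""
    joint, ablation = [], []
    for s in seeds:
        joint.append(_benefit_run(seed_offset + s, s, w1=1.0))
        ablation.append(_benefit_run(seed_offset + s, s, w1=0.0))
    return {
        "joint_f1": joint,
        "ablation_f1": ablation,
        "joint_mean_f1": sum(joint) / len(joint),
        "ablation_mean_f1": sum(ablation) / len(ablation),
        "n_seeds": len(joint),
    }
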