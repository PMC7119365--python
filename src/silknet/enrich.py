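"""Hypergeometric over-representation tests and the cross-stage
functional-shift comparison of up- vs down-regulated gene sets."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust


def hypergeom_enrich(
    study_genes,
    universe_genes,
    annotation: dict[str, set[str]],
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term with BH across tested terms.

    The universe is restricted to annotated genes; rows are ordered by
    (p, term).  Columns: term, k, n, K, N, p, adj_p, fold_enrichment.
    """
    study = set(study_genes)
    universe = set(universe_genes)
    outside = sorted(study - universe)
    if outside:
        raise ValueError(f"study genes outside universe: {outside[:5]}")
    annotated = {g for g in universe if annotation.get(g)}
    n_universe = len(annotated)
    study_annotated = study & annotated
    n_study = len(study_annotated)

    term_genes: dict[str, set[str]] = {}
    for g in annotated:
        for t in annotation[g]:
            term_genes.setdefault(t, set()).add(g)

    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        big_k = len(members)
        if big_k < min_term_size:
            continue
        k = len(members & study_annotated)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_study))
        fold = (
            (k / n_study) / (big_k / n_universe) if n_study and big_k else float("nan")
        )
        rows.append(
            {"term": term, "k": k, "n": n_study, "K": big_k, "N": n_universe,
             "p": min(p, 1.0), "fold_enrichment": fold}
        )
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p", "fold_enrichment"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "term"], ignore_index=True)
    else:
        out["adj_p"] = pd.Series(dtype=float)
    return out


def functional_shift(
    up_enrich_by_stage: dict[str, pd.DataFrame],
    down_enrich_by_stage: dict[str, pd.DataFrame],
    stages: list[str],
    sig_cut: float = 0.05,
) -> pd.DataFrame:
    """Terms persistently enriched in one direction only.

    A term is up-shifted iff adj_p < ``sig_cut`` in the up-set at every stage
    and at no stage in the down-set; symmetrically for down-shifted.
    """
    for st in stages:
        if st not in up_enrich_by_stage or st not in down_enrich_by_stage:
            raise ValueError(f"missing enrichment results for stage {st!r}")

    def sig_terms(res: pd.DataFrame) -> set[str]:
        if len(res) == 0:
            return set()
        return set(res.loc[res["adj_p"] < sig_cut, "term"])

    up_sets = [sig_terms(up_enrich_by_stage[st]) for st in stages]
    down_sets = [sig_terms(down_enrich_by_stage[st]) for st in stages]
    up_all = set.intersection(*up_sets) if up_sets else set()
    up_never_down = up_all - set.union(*down_sets) if down_sets else up_all
    down_all = set.intersection(*down_sets) if down_sets else set()
    down_never_up = down_all - set.union(*up_sets) if up_sets else down_all

    rows = [{"term": t, "direction": "up"} for t in sorted(up_never_down)]
    rows += [{"term": t, "direction": "down"} for t in sorted(down_never_up)]
    return pd.DataFrame(rows, columns=["term", "direction"])
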