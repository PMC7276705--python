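"""Mutation annotation, enrichment scores E, and functional scores F.

For every single-base substitution in the CDS the enrichment is the log2
ratio of wild-type-normalised counts between a selected and a control
population::

    E = log2[ ((C_sel,mut + p) / (C_sel,wt + p)) /
              ((C_ctrl,mut + p) / (C_ctrl,wt + p)) ]

with pseudocount ``p`` (0.1 by default).  Enrichments are converted to
functional scores by a per-replicate linear rescaling that anchors the
median synonymous mutation at F = 1 (function retained) and the median
nonsense mutation at F = 0 (function lost).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .fragproc import CountTable
from .reference import BASES, MutationKey, ReferenceAmplicon, STOP

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
STOP_LOSS = "stop_loss"

# Alt-base order used by the vectorised enrichment table: for each CDS
# position the three non-reference bases in BASES order.
MUTATION_INDEX_NAMES = ["pos", "ref", "alt"]


@dataclasses.dataclass(frozen=True)
class MutationAnnotation:
    """Codon-level consequence of one substitution in a wild-type context."""

    effect_class: str
    codon_index: int  # 0-based codon within the CDS
    ref_aa: str
    alt_aa: str
    residue: int  # 1-based precursor residue number
    cds_pos: int  # 1-based CDS coordinate of the substituted base


def annotate_mutation(key: MutationKey, ref: ReferenceAmplicon) -> MutationAnnotation:
    """Classify a substitution with the codon recomputed in an otherwise
    wild-type context."""
    if not ref.in_cds(key.pos):
        raise ValueError(f"position {key.pos} is outside the CDS")
    if ref.sequence[key.pos] != key.ref:
        raise ValueError(
            f"reference base at {key.pos} is {ref.sequence[key.pos]}, not {key.ref}"
        )
    if key.alt == key.ref or key.alt not in BASES:
        raise ValueError(f"invalid alternate base {key.alt!r}")
    offset = key.pos - ref.cds_start
    codon_index, within = divmod(offset, 3)
    ref_codon = ref.codon(codon_index)
    alt_codon = ref_codon[:within] + key.alt + ref_codon[within + 1 :]
    ref_aa = ref.genetic_code[ref_codon]
    alt_aa = ref.genetic_code[alt_codon]
    if ref_aa == alt_aa:
        effect = SYNONYMOUS
    elif alt_aa == STOP:
        effect = NONSENSE
    elif ref_aa == STOP:
        effect = STOP_LOSS
    else:
        effect = MISSENSE
    return MutationAnnotation(
        effect_class=effect,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        residue=codon_index + 1,
        cds_pos=offset + 1,
    )


def mutation_catalog(ref: ReferenceAmplicon) -> pd.DataFrame:
    """Annotation table for every possible CDS substitution.

    Indexed by (pos, ref, alt) with pos the 0-based amplicon coordinate;
    columns: effect_class, residue, cds_pos, ref_aa, alt_aa.
    """
    rows = []
    for pos in range(ref.cds_start, ref.cds_end):
        ref_base = ref.sequence[pos]
        for alt in BASES:
            if alt == ref_base:
                continue
            ann = annotate_mutation(MutationKey(pos, ref_base, alt), ref)
            rows.append(
                (pos, ref_base, alt, ann.effect_class, ann.residue, ann.cds_pos,
                 ann.ref_aa, ann.alt_aa)
            )
    frame = pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "effect_class", "residue", "cds_pos",
                 "ref_aa", "alt_aa"],
    )
    return frame.set_index(MUTATION_INDEX_NAMES)


def compute_enrichment(
    sel: CountTable, ctrl: CountTable, pseudocount: float = 0.1
) -> pd.DataFrame:
    """Per-mutation log2 enrichment of selected over control counts.

    Returns a frame indexed by (pos, ref, alt) over all CDS substitutions,
    with columns ``E``, ``sel_count`` and ``ctrl_count`` (the raw fragment
    counts before pseudocounting).  With ``pseudocount`` zero, mutations with
    a zero count anywhere yield infinite or undefined E; the default 0.1
    keeps every value finite.
    """
    if sel.ref.sequence != ctrl.ref.sequence:
        raise ValueError("selected and control tables use different references")
    ref = sel.ref
    lo, hi = ref.cds_start, ref.cds_end
    ref_idx = ref.base_index()[lo:hi]
    sel_counts = sel.counts[lo:hi]
    ctrl_counts = ctrl.counts[lo:hi]
    n = hi - lo
    sel_wt = sel_counts[np.arange(n), ref_idx].astype(float)
    ctrl_wt = ctrl_counts[np.arange(n), ref_idx].astype(float)

    pos_col, ref_col, alt_col = [], [], []
    e_col, selc_col, ctrlc_col = [], [], []
    with np.errstate(divide="ignore", invalid="ignore"):
        for b, base in enumerate(BASES):
            mask = ref_idx != b
            smut = sel_counts[:, b].astype(float)
            cmut = ctrl_counts[:, b].astype(float)
            e = np.log2(
                ((smut + pseudocount) / (sel_wt + pseudocount))
                / ((cmut + pseudocount) / (ctrl_wt + pseudocount))
            )
            idx = np.nonzero(mask)[0]
            pos_col.append(idx + lo)
            ref_col.append(np.array(list(ref.sequence[lo:hi]))[idx])
            alt_col.append(np.full(idx.size, base))
            e_col.append(e[idx])
            selc_col.append(smut[idx])
            ctrlc_col.append(cmut[idx])
    frame = pd.DataFrame(
        {
            "pos": np.concatenate(pos_col),
            "ref": np.concatenate(ref_col),
            "alt": np.concatenate(alt_col),
            "E": np.concatenate(e_col),
            "sel_count": np.concatenate(selc_col),
            "ctrl_count": np.concatenate(ctrlc_col),
        }
    )
    return frame.set_index(MUTATION_INDEX_NAMES).sort_index()


def filter_by_input(
    enrichments: Mapping[str, pd.DataFrame], min_mean_ctrl: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Keep mutations whose mean control fragment count across replicates is
    at least ``min_mean_ctrl`` (the boundary value itself is retained)."""
    if not enrichments:
        raise ValueError("no replicate enrichment tables given")
    ctrl = pd.concat(
        {name: df["ctrl_count"] for name, df in enrichments.items()}, axis=1
    )
    keep = ctrl.mean(axis=1) >= min_mean_ctrl
    keep_index = keep[keep].index
    return {
        name: df.loc[df.index.intersection(keep_index)].copy()
        for name, df in enrichments.items()
    }


def scale_to_functional(
    enrichment: pd.DataFrame,
    catalog: pd.DataFrame,
    selection: str = "lambda",
    malt_formula: str = "prose",
    replicate: str = "",
) -> pd.DataFrame:
    """Linearly rescale enrichments so the syn/stop medians anchor F at 1/0.

    The anchors are computed over this replicate's mutations only;
    stop-loss mutations are scored but excluded from both anchor sets.
    ``malt_formula="as-printed"`` reproduces the alternative published form
    of the maltodextrin score, which swaps the anchors so the median
    synonymous mutation maps to 0 and the median nonsense mutation to 1.
    """
    if selection not in ("lambda", "malt"):
        raise ValueError(f"unknown selection {selection!r}")
    if malt_formula not in ("prose", "as-printed"):
        raise ValueError(f"unknown malt formula {malt_formula!r}")
    effects = catalog.loc[enrichment.index, "effect_class"]
    syn = enrichment.loc[(effects == SYNONYMOUS).to_numpy(), "E"]
    stop = enrichment.loc[(effects == NONSENSE).to_numpy(), "E"]
    tag = f" in replicate {replicate}" if replicate else ""
    if syn.empty or stop.empty:
        raise ValueError(
            f"need at least one synonymous and one nonsense mutation{tag}"
        )
    med_syn = float(syn.median())
    med_stop = float(stop.median())
    if med_syn == med_stop:
        raise ValueError(
            f"synonymous and nonsense enrichment medians coincide{tag}; "
            "anchors are degenerate (a midpoint fallback must be chosen "
            "explicitly by the caller)"
        )
    out = enrichment.copy()
    if selection == "malt" and malt_formula == "as-printed":
        out["F"] = (out["E"] - med_syn) / (med_stop - med_syn)
    else:
        out["F"] = (out["E"] - med_stop) / (med_syn - med_stop)
    out["effect_class"] = effects
    out["residue"] = catalog.loc[out.index, "residue"]
    out["cds_pos"] = catalog.loc[out.index, "cds_pos"]
    return out


def average_replicates(scored: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of F over the replicates where each mutation passed
    filtering, with the replicate count reported."""
    if not scored:
        raise ValueError("no scored replicate tables given")
    f_cols = pd.concat({name: df["F"] for name, df in scored.items()}, axis=1)
    meta = pd.concat(
        [df[["effect_class", "residue", "cds_pos"]] for df in scored.values()]
    )
    meta = meta[~meta.index.duplicated()]
    out = pd.DataFrame(
        {
            "F_mean": f_cols.mean(axis=1),
            "n_replicates": f_cols.notna().sum(axis=1).astype(int),
        }
    )
    for name in f_cols.columns:
        out[f"F_{name}"] = f_cols[name]
    out = out.join(meta.loc[out.index])
    return out.sort_index()
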