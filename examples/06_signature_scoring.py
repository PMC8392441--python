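"""Score the published 22-gene quiescence signature on a synthetic cohort.

The signature score is the standardised difference between the mean log2
expression of the up- and down-regulated signature genes; here it is
computed on simulated expression and compared between ER strata.
"""

import numpy as np
import pandas as pd

from qsig import select, sigscore

evidence = select.load_reference_evidence()
signature = select.selection_to_signature(evidence,
                                          provenance="published 22-gene set")
print(f"signature: {len(signature.up)} up genes, "
      f"{len(signature.down)} down genes (e.g. {signature.up[:4]})")

# synthetic log2 expression for 120 samples; ER+ samples shifted upwards on
# the signature genes, emulating the higher quiescence scores of ER+ tumours
rng = np.random.default_rng(41)
genes = list(evidence.index) + [f"bg{i}" for i in range(100)]
er_pos = rng.random(120) < 0.6
expr = pd.DataFrame(rng.normal(8.0, 1.0, size=(len(genes), 120)),
                    index=genes, columns=[f"s{i}" for i in range(120)])
expr.loc[evidence.index, er_pos] += 0.6

scores = sigscore.signature_score(expr, signature)
print(f"scores: mean {scores['score'].mean():+.2e}, "
      f"SD {scores['score'].std(ddof=0):.2f} (standardised by contract)")

stat, p = sigscore.score_vs_group(scores["score"].to_numpy(), er_pos)
print(f"ER+ vs ER- rank-sum p = {p:.2e} "
      "(ER+ samples carry the planted upward shift)")

rho, p_rho = sigscore.spearman_corr(scores["score"],
                                    -scores["raw"] + rng.normal(0, 0.3, 120))
print(f"Spearman check against a noisy inverted copy: rho = {rho:.2f}")
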