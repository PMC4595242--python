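"""Resolve causes from two blinded reviewers plus an arbiter.

The cause two of the three reviewers agree on is assigned; three different
opinions make the death unclassifiable.  The summary mirrors the consensus
accounting a validation study reports.
"""
import pandas as pd

from neoval import adjudicate_table
from neoval.pipeline import summarize_final_table

reviews = pd.DataFrame(
    [
        ("n01", "R1", "primary", "prematurity_complications"),
        ("n01", "R2", "primary", "prematurity_complications"),
        ("n02", "R1", "primary", "sepsis"),
        ("n02", "R2", "primary", "birth_asphyxia"),
        ("n02", "R3", "arbiter", "birth_asphyxia"),
        ("n03", "R1", "primary", "sepsis"),
        ("n03", "R2", "primary", "tetanus"),
        ("n03", "R3", "arbiter", "meningitis"),
    ],
    columns=["case_id", "reviewer_id", "round", "cause"],
)

final = adjudicate_table(reviews)
print(final.to_string(index=False))

s = summarize_final_table(final)
print(f"\n{s.n_reviewed} reviewed: {s.n_consensus} consensus "
      f"({s.pct_consensus}%), {s.n_arbiter_agrees_one} settled by the "
      f"arbiter, {s.n_all_differ} unclassifiable")
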