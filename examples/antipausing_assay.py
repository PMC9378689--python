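"""Quantify a radiolabeled transcription assay and score conservation.

Simulates gel lanes for a panel of put mutants with known anti-pausing
activities (plus the WT and put- anchor lanes), recovers the activities
via cytosine-calibrated paused fractions, classifies the mutants, and
scores per-residue conservation on a toy alignment.
"""

from io import StringIO

import putec

truth = {"U20C": 0.95, "A8G": 0.55, "G35A": 0.05, "U28C": 0.12}
gel = putec.make_gel_dataset(truth, noise_cv=0.05, n_replicates=3, seed=42)
results = putec.activities_from_lanes(list(gel.lanes))

print(f"{'mutant':<8s} {'activity':>9s} {'SEM':>7s} {'class':>14s}")
for r in results:
    sem = f"{r.sem:.3f}" if r.sem is not None else "  n/a"
    print(f"{r.label:<8s} {r.mean_activity:>9.3f} {sem:>7s} {r.activity_class:>14s}")

print()
print("WT and put- anchor the scale at 1 and 0 by construction; mutants below")
print("20% activity are 'inactivating', above 90% 'inert', the rest 'other'.")

alignment = StringIO(
    ">HK022\nAGACG\n" +
    "".join(f">put{i}\n{row}\n" for i, row in enumerate(
        ["AGACG", "AGACG", "AGACG", "AGUCG", "AGUCG",
         "ACACG", "ACUCG", "AAACG", "UGGCG"])))
profile = putec.conservation_profile(alignment, "HK022", fmt="fasta")
print(f"\nconservation scores over {profile.n_sequences} put sequences: "
      f"{profile.scores}")
print("each score counts the sequences matching the reference base at that")
print("position; high scores mark residues under selective pressure.")
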