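"""Putative annotation of a small peak list.

Builds a three-feature tsv peak list, parses it, and matches each feature's
possible adduct-derived neutral masses against the built-in metabolic model.
Printed: the compound matches with their adducts and ppm errors. A feature
can annotate several compounds (e.g. a glucose [M+H]+ ion is also a lactate
dimer [2M+H]+), which is exactly the ambiguity the pathway-level statistics
are designed to absorb.
"""

import tempfile
from pathlib import Path

import pathmeta as pm

peaklist = (
    "mz\tp_value\trt\tintensity\n"
    "181.070664\t0.004\t65.1\t2.1e5\n"   # glucose [M+H]+
    "147.076419\t0.030\t142.8\t8.9e4\n"  # glutamine [M+H]+
    "500.304149\t0.650\t301.5\t4.0e4\n"  # taurochenodeoxycholate [M+H]+, not significant
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo_study.tsv"
    path.write_text(peaklist)
    study = pm.read_feature_table(path, dialect="generic", mode="positive")

model = pm.builtin_toy_model()
index = pm.match_study(study, model)

print(f"{len(study.features)} features -> {len(index.matches)} compound matches")
for match in index.matches:
    flag = "significant" if match.significant else "reference"
    print(
        f"  mz {match.feature.mz:10.6f}  {match.adduct_name:>6s} -> "
        f"{match.compound_id:25s} ({match.ppm_error:+.2f} ppm, {flag})"
    )
print(
    "\nCompound sets: "
    f"{len(index.matched_reference_compounds)} in the reference universe, "
    f"{len(index.matched_significant_compounds)} significant (p < "
    f"{study.params.p_cutoff})."
)
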