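"""Diagnosis -> relapse clonal inference from bulk VAFs.

Plants the classic relapse scenario in which a biallelic (UPD-homozygous)
WT1 subclone, present at low level at diagnosis inside the UBTF-TD founder
clone, expands to drive relapse.  The analysis corrects VAFs for copy
number, nests variants by the pigeonhole rule, classifies WT1 allelic
status at each timepoint, and labels the relapse pattern.
"""

from ubtftd import CNState, PlantedClone, analyze_patient, simulate_paired_timepoints

clones = [
    PlantedClone("founder", None, [("UBTF-TD.1", "UBTF-TD", CNState.diploid_het())],
                 {"diagnosis": 0.90, "progression": 0.95}),
    PlantedClone("wt1_hom", "founder", [("WT1.1", "WT1", CNState.upd_hom())],
                 {"diagnosis": 0.05, "progression": 0.90}),
]
variants, truth = simulate_paired_timepoints(clones, depth=500, seed=3)
report = analyze_patient(variants)

print("variant status:", report.variant_status)
print("WT1 class     :", report.wt1_class)
print("relapse       :", report.relapse_pattern)
print("\nfishplot matrix (inclusive clone prevalences):")
print(report.tree.fishplot_frame().to_string(index=False))
# 'bi_alt_preexisting': the homozygous WT1 clone driving relapse was already
# detectable (above the 1% VAF floor) at diagnosis.
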