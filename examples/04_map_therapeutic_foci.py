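"""Map MeSH condition terms to high-level therapeutic foci.

Each term's tree numbers are truncated to their top-level code (e.g.
C04 → Neoplasms); a trial's foci are the deduplicated union over its terms,
and cohort tabulation counts focus occurrences (multiple foci per trial).
"""

from termtrials import assign_trial_foci, generate_mesh_fixture, map_term_to_foci, tabulate_foci

tree = generate_mesh_fixture()

print("breast cyst ->", set(map_term_to_foci("breast cyst", tree)))
# resolves through the tree hierarchy to its top-level heading, Neoplasms

print("stroke ->", sorted(map_term_to_foci("stroke", tree)))
# a term can sit under two branches and contribute both foci

trials = [
    assign_trial_foci("NCT1", ["breast cyst", "lung neoplasms"], tree),
    assign_trial_foci("NCT2", ["stroke"], tree),
    assign_trial_foci("NCT3", [], tree),
]
print(tabulate_foci(trials))
# NCT1 counts once under Neoplasms (dedup); NCT3 appears as "No assigned
# foci"; percentages are of total occurrences, not unique trials
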