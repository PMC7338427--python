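"""Generate a small synthetic two-arm cohort on disk.

Writes FCS event files (five tubes per subject), per-subject ground-truth
sidecars and a manifest CSV, then prints what was produced.  The shipped
presets encode the published cohort medians for the NBS and healthy-control
arms; here we draw 3 subjects per arm to keep the run small.
"""

import tempfile
from pathlib import Path

from tmaturity import default_spillover, load_preset, simulate_cohort

out = Path(tempfile.mkdtemp(prefix="tmaturity_cohort_"))
rows = simulate_cohort(load_preset("nbs"), load_preset("control"), seed=1,
                       out_dir=out, fmt="fcs", n_events=15_000,
                       n_subjects=3, spill=default_spillover())

print(f"cohort written to {out}")
print(f"  {len(rows)} event files (subjects x 5 tubes), "
      f"{len({r['subject_id'] for r in rows})} subjects")
print("  manifest.csv columns: subject_id, group, tube_id, events_path, truth_path")
first = rows[0]
print(f"  e.g. {first['subject_id']} ({first['group']} arm) tube "
      f"{first['tube_id']} -> {first['events_path']}")
truth = (out / first["truth_path"]).read_text().splitlines()
print("  ground-truth sidecar head (true per-subject fractions/counts):")
for line in truth[:5]:
    print("   ", line)
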