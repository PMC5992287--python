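"""Build the three vibrotactile oddball schedules and tally them.

The VT2 screening run mixes frequent left-wrist standards with rare
right-wrist deviants; VT3 adds a foot standard and splits deviants over
both wrists in attended-wrist blocks; communication blocks reuse the VT3
statistics with left=yes / right=no.
"""

from collections import Counter

from vibrotap import build_comm_schedule, build_vt2_schedule, build_vt3_schedule

vt2 = build_vt2_schedule(seed=1)
print(f"VT2: {len(vt2)} stimuli, {vt2.duration_s / 60:.1f} min")
print("     tally:", Counter((e.site, e.role) for e in vt2.events))

vt3 = build_vt3_schedule(seed=1)
print(f"VT3: {len(vt3)} stimuli in {len(vt3.blocks)} blocks")
for start, stop, attended in vt3.blocks:
    ev = vt3.events[start:stop]
    print(f"     block attending {attended}: "
          f"{sum(e.is_target for e in ev)} targets, "
          f"{sum(e.role == 'deviant' and not e.is_target for e in ev)} "
          f"non-targets, {sum(e.role == 'standard' for e in ev)} standards")

comm = build_comm_schedule(n_questions=6, seed=1)
print(f"COMM: {len(comm.blocks)} question blocks x "
      f"{comm.blocks[0][1]} stimuli (30 s each); "
      "attend left wrist = yes, right wrist = no")

# Exact counts (60/480 deviants, 15/15/90 per VT3 block) are guaranteed by
# construction, so any deviation downstream indicates a processing bug, not
# sampling noise.
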