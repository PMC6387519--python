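"""Length-preference peak detection on unit-length histograms.

SSR abundance normally decays with repeat length. A "length preference" is
a local bump: abundance rises over consecutive unit lengths, reaches a
maximum, and falls back below the level at the bump's start. Bumps must
span >= 4 unit lengths and start above abundance 10.
"""

from ssrscape import detect_length_preference

decaying = {2: 500, 3: 240, 4: 120, 5: 60, 6: 30, 7: 15}
print("monotone histogram ->", detect_length_preference(decaying))

bumped = {2: 500, 3: 100, 4: 40, 5: 60, 6: 90, 7: 30, 8: 10}
peaks = detect_length_preference(bumped)
for p in peaks:
    print(
        f"peak: start unit {p.peak_start} (abundance {p.start_abundance}), "
        f"maximum at unit {p.maxima}, ends at unit {p.end}, span {p.span}"
    )
# The bump from unit 4 to 7 is reported; its start abundance (40) exceeds 10
# and it spans 4 consecutive unit lengths, so it passes both filters.

weak = {2: 8, 3: 4, 4: 6, 5: 9, 6: 3}
print("weak bump (start abundance <= 10) ->", detect_length_preference(weak))
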