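"""Named analysis presets: TSS windows and replicate-consensus rules.

Window offsets are in the transcription direction relative to the TSS
(negative = upstream) and are resolved per strand by the callers.
"""

from __future__ import annotations

# name -> (upstream_bp, downstream_bp), i.e. window = [TSS - up, TSS + down)
WINDOW_PRESETS: dict[str, tuple[int, int]] = {
    "promoter": (300, 100),      # ChEC peak-to-promoter assignment window
    "h4k12ac_tss": (100, 200),   # H4K12ac / H3 ratio window
    "tfiib_tss": (200, 100),     # TFIIB promoter signal window
    "tata_scan": (200, 0),       # TATA consensus scan window
}

# assay -> (k, n): promoter counted bound when bound in >= k of n replicates
CONSENSUS_PRESETS: dict[str, tuple[int, int]] = {
    "chec": (4, 6),
    "chip": (1, 2),
}
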