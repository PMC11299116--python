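#!/usr/bin/env python
"""Descriptive share statistics: when do the cases occur?

Computes per-month and per-sanfu-period occurrence shares for the synthetic
series, and reproduces the published shares from the original surveillance
study's printed totals as a cross-check of the share arithmetic
(round-half-up to two decimals). Writes results/descriptives.json.
"""

import json
from pathlib import Path

from heatlag import io
from heatlag.prediction import descriptive_shares, shares_from_totals
from heatlag.reference import MONTHLY_COUNTS, SANFU_COUNTS

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    feats = io.read_daily_csv(OUT / "features.csv", require_count=True)
    synth = descriptive_shares(feats)
    published = {
        "monthly_shares": shares_from_totals(MONTHLY_COUNTS),
        "sanfu_shares": shares_from_totals(SANFU_COUNTS),
    }
    (OUT / "descriptives.json").write_text(
        json.dumps({"synthetic": synth, "published_totals": published}, indent=2)
    )
    print("synthetic monthly shares (%):", synth["monthly_shares"])
    print("synthetic sanfu shares (%):", synth.get("sanfu_shares"))
    print("published monthly shares (%):", published["monthly_shares"])
    print("published sanfu shares (%):", published["sanfu_shares"])
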