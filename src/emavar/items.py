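"""Default EMA item metadata.

The assessment battery has 32 momentary items grouped into six clinical
domains: suicide risk (items 1-6), wish to live/die (7-8), social support
(9-12), social withdrawal (13-15), sleep (16-25) and appetite (26-32).
Items phrased so that a *higher* raw answer means a *better* state (e.g.
"I am full of hope", "my wish to live is", sleep-quality items) are marked
reverse-worded; rescaling flips them so that 100 always means the worst
condition.  Sleep and suicide-risk items carry a higher sampling weight
because they are prompted more often than the rest.
"""

from __future__ import annotations

import pandas as pd

DOMAINS = [
    "suicide_risk",
    "wish_to_live",
    "social_support",
    "social_withdrawal",
    "sleep",
    "appetite",
]

#: item_id ranges per domain (inclusive)
DOMAIN_ITEMS = {
    "suicide_risk": range(1, 7),
    "wish_to_live": range(7, 9),
    "social_support": range(9, 13),
    "social_withdrawal": range(13, 16),
    "sleep": range(16, 26),
    "appetite": range(26, 33),
}

#: items whose raw scale runs "higher = better" and must be flipped
_REVERSE = {4, 7, 13, 14, 21, 22, 26, 28, 29, 30, 31}

#: raw response ranges per domain (instrument-style scales)
_RANGES = {
    "suicide_risk": (0.0, 10.0),
    "wish_to_live": (0.0, 10.0),
    "social_support": (1.0, 5.0),
    "social_withdrawal": (1.0, 5.0),
    "sleep": (0.0, 4.0),
    "appetite": (1.0, 5.0),
}

#: relative prompting weight: sleep and suicide items are asked more often
_HIGH_WEIGHT_DOMAINS = {"sleep", "suicide_risk"}
HIGH_WEIGHT = 5.0


def default_item_meta() -> pd.DataFrame:
    """Metadata table for the 32 default items.

    Columns: item_id, domain, raw_min, raw_max, reverse_worded, weight.
    """
    rows = []
    for domain, ids in DOMAIN_ITEMS.items():
        lo, hi = _RANGES[domain]
        w = HIGH_WEIGHT if domain in _HIGH_WEIGHT_DOMAINS else 1.0
        for i in ids:
            rows.append(
                dict(
                    item_id=i,
                    domain=domain,
                    raw_min=lo,
                    raw_max=hi,
                    reverse_worded=i in _REVERSE,
                    weight=w,
                )
            )
    meta = pd.DataFrame(rows)
    if sorted(meta["item_id"]) != list(range(1, 33)):  # pragma: no cover
        raise RuntimeError("default item metadata must cover items 1..32")
    return meta
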