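"""Storefront observation records shared across the pipeline."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Tuple


@dataclass(frozen=True)
class StoreRecord:
    """One storefront observation.

    A record carries everything any pipeline stage may need: the raw name and
    surveyor taxonomy fields (meta category, granular tags, dine-in /
    quick-bites flags) used by taxonomy mapping; a WGS84 point location used
    by spatial binning; inspection dates and an optional out-of-business date
    used to derive operating intervals; and optional service-description and
    venue tags carried by restaurant inspection extracts.
    """

    record_id: str
    name: str
    meta_category: str = ""
    tags: FrozenSet[str] = frozenset()
    flags: FrozenSet[str] = frozenset()
    survey_date: Optional[dt.date] = None
    longitude: float = 0.0
    latitude: float = 0.0
    inspection_dates: Tuple[dt.date, ...] = field(default_factory=tuple)
    out_of_business_date: Optional[dt.date] = None
    service_description: Optional[str] = None
    venue_tag: Optional[str] = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValueError(f"record {self.record_id!r}: name must be non-empty")
        dates = tuple(self.inspection_dates)
        if list(dates) != sorted(dates):
            raise ValueError(
                f"record {self.record_id!r}: inspection_dates must be ascending"
            )
        if self.out_of_business_date is not None and dates:
            if self.out_of_business_date < dates[-1]:
                raise ValueError(
                    f"record {self.record_id!r}: out_of_business_date precedes "
                    "the last inspection date"
                )
        object.__setattr__(self, "tags", frozenset(self.tags))
        object.__setattr__(self, "flags", frozenset(self.flags))
        object.__setattr__(self, "inspection_dates", dates)
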