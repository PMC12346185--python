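# Reference weekly portions for the five animal-protein food groups used by
# level-1 advice.  Values are editable placeholders in the spirit of the
# Eatwell Guide / British Nutrition Foundation portion lists (oily fish about
# once a week, two portions of fish in total, limited red and processed meat).
schema_version: 1
references:
  oily_fish:      {portions_per_week: 1, portion_size: "140 g cooked fillet"}
  nonoily_fish:   {portions_per_week: 1, portion_size: "140 g cooked fillet"}
  poultry:        {portions_per_week: 2, portion_size: "120 g cooked, skinless"}
  red_meat:       {portions_per_week: 2, portion_size: "70 g cooked"}
  processed_meat: {portions_per_week: 1, portion_size: "50 g"}
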