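{
  "nodes": [
    {"id": 0, "item": "tea_with_sugar", "threshold": 3, "left": 1, "right": 2,
     "class": "omnivore", "dist": {"health_conscious": 0.33, "omnivore": 0.41, "sweet_tooth": 0.26}},
    {"id": 1, "item": "vegetables", "threshold": 8, "left": 3, "right": 4,
     "class": "health_conscious", "dist": {"health_conscious": 0.62, "omnivore": 0.27, "sweet_tooth": 0.11}},
    {"id": 2, "item": "roast_chicken", "threshold": 7, "left": 5, "right": 6,
     "class": "omnivore", "dist": {"health_conscious": 0.18, "omnivore": 0.48, "sweet_tooth": 0.34}},
    {"id": 3, "item": null, "threshold": null, "left": null, "right": null,
     "class": "omnivore", "dist": {"health_conscious": 0.35, "omnivore": 0.45, "sweet_tooth": 0.20}},
    {"id": 4, "item": null, "threshold": null, "left": null, "right": null,
     "class": "health_conscious", "dist": {"health_conscious": 0.78, "omnivore": 0.15, "sweet_tooth": 0.07}},
    {"id": 5, "item": null, "threshold": null, "left": null, "right": null,
     "class": "sweet_tooth", "dist": {"health_conscious": 0.14, "omnivore": 0.30, "sweet_tooth": 0.56}},
    {"id": 6, "item": null, "threshold": null, "left": null, "right": null,
     "class": "omnivore", "dist": {"health_conscious": 0.20, "omnivore": 0.61, "sweet_tooth": 0.19}}
  ],
  "item_subset": [
    "tea_with_sugar", "vegetables", "roast_chicken", "ham", "tomatoes",
    "strawberries", "green_olives", "banana", "sweet_coffee_drinks",
    "coffee_with_sugar", "fruit", "mushroom", "spinach", "potatoes"
  ]
}
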