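{
  "name": "composite-morningness-default-key",
  "description": "Scoring key for a 13-item Composite Morningness Questionnaire: ten 4-option items and three 5-option items, option points ascending toward morningness, totals ranging 13-55. Synthetic stand-in item wordings; replace this file to score the published instrument verbatim.",
  "items": [
    {"id": "cmq01", "prompt": "Preferred rising time if entirely free to plan the day", "points": [1, 2, 3, 4, 5]},
    {"id": "cmq02", "prompt": "Preferred bedtime if entirely free to plan the evening", "points": [1, 2, 3, 4, 5]},
    {"id": "cmq03", "prompt": "Ease of getting up in the morning", "points": [1, 2, 3, 4]},
    {"id": "cmq04", "prompt": "Alertness during the first half hour after waking", "points": [1, 2, 3, 4]},
    {"id": "cmq05", "prompt": "Tiredness during the first half hour after waking", "points": [1, 2, 3, 4]},
    {"id": "cmq06", "prompt": "Appetite during the first half hour after waking", "points": [1, 2, 3, 4]},
    {"id": "cmq07", "prompt": "Preferred time for one hour of demanding exercise", "points": [1, 2, 3, 4]},
    {"id": "cmq08", "prompt": "Evening tiredness and consequent need for sleep", "points": [1, 2, 3, 4, 5]},
    {"id": "cmq09", "prompt": "Time of day of feeling at one's best", "points": [1, 2, 3, 4]},
    {"id": "cmq10", "prompt": "Ease of a hypothetical 06:00 workout", "points": [1, 2, 3, 4]},
    {"id": "cmq11", "prompt": "Self-rated morning-type versus evening-type", "points": [1, 2, 3, 4]},
    {"id": "cmq12", "prompt": "Preferred timing of two daily hours of hard work", "points": [1, 2, 3, 4]},
    {"id": "cmq13", "prompt": "Dependence on an alarm clock to wake at 06:00", "points": [1, 2, 3, 4]}
  ]
}
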