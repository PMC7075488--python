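journal,met,not_met
Frontiers in Psychology,5,4
Journal of Personality Assessment,4,5
Psychological Assessment,8,15
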