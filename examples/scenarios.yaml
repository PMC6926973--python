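# What-if scenarios against a network learned on survey11-style data.
# Evidence values may be state labels or the directives "!max" / "!min",
# which resolve to the last / first state of the variable's ordered list.
- name: mid_pocket_money
  evidence: {Pocket_Money: medium}
  target: Obesity_Level=obese
- name: mid_pocket_money_low_wealth
  evidence: {Pocket_Money: medium, Wealth: low}
  target: Obesity_Level=obese
- name: max_sitting_time
  evidence: {Sitting_Time_Study: "!max"}
  target: Obesity_Level=obese
- name: parents_education_split
  evidence: {Education_Father: "!max", Education_Mother: "!min"}
  target: Obesity_Level=obese
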