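# Data dictionary for the wave-table schema.
#
# Each variable is declared with its type and instrument-defined bounds so
# that unit scaling is dataset-independent.  Ordinal/continuous variables are
# scaled to [0, 1] with (lo, hi); categorical variables are one-hot encoded;
# standardized variables are z-scored with the constants in
# standardization.yaml instead of being unit-scaled.
#
# The questionnaire item ranges below are the assumed harmonization for
# synthetic cohorts; they are configuration, not claims about any external
# survey's coding.

variables:
  age:            {type: continuous, lo: 40, hi: 120}
  sex:            {type: ordinal, lo: 0, hi: 1}
  marital_status: {type: categorical,
                   categories: [married, partnered, single, divorced, separated, widowed]}
  education:      {type: ordinal, lo: 1, hi: 7}
  bmi:            {type: continuous, lo: 10, hi: 60}

  hearing_left:   {type: ordinal, lo: 1, hi: 5}
  hearing_right:  {type: ordinal, lo: 1, hi: 5}
  vision_far:     {type: ordinal, lo: 1, hi: 5}
  vision_near:    {type: ordinal, lo: 1, hi: 5}

  sppb_balance:    {type: ordinal, lo: 0, hi: 4}
  sppb_gait:       {type: ordinal, lo: 0, hi: 4}
  sppb_chair:      {type: ordinal, lo: 0, hi: 4}
  sppb_gait_time:  {type: continuous, lo: 0, hi: 60}
  sppb_chair_time: {type: continuous, lo: 0, hi: 60}

  moca_total:     {type: standardized, lo: 0, hi: 30}
  phq9_total:     {type: standardized, lo: 0, hi: 27}

  sf12_q1:  {type: ordinal, lo: 1, hi: 5}
  sf12_q2:  {type: ordinal, lo: 1, hi: 3}
  sf12_q3:  {type: ordinal, lo: 1, hi: 3}
  sf12_q4:  {type: ordinal, lo: 1, hi: 2}
  sf12_q5:  {type: ordinal, lo: 1, hi: 2}
  sf12_q6:  {type: ordinal, lo: 1, hi: 2}
  sf12_q8:  {type: ordinal, lo: 1, hi: 5}
  sf12_q10: {type: ordinal, lo: 1, hi: 6}
  sf12_q11: {type: ordinal, lo: 1, hi: 6}

  iadl_q1: {type: ordinal, lo: 1, hi: 3}
  iadl_q2: {type: ordinal, lo: 1, hi: 3}
  iadl_q3: {type: ordinal, lo: 1, hi: 3}
  iadl_q4: {type: ordinal, lo: 1, hi: 3}
  iadl_q5: {type: ordinal, lo: 1, hi: 3}
  iadl_q7: {type: ordinal, lo: 1, hi: 3}
  iadl_q8: {type: ordinal, lo: 1, hi: 3}

  ucla_q1:  {type: ordinal, lo: 1, hi: 4}
  ucla_q2:  {type: ordinal, lo: 1, hi: 4}
  ucla_q4:  {type: ordinal, lo: 1, hi: 4}
  ucla_q11: {type: ordinal, lo: 1, hi: 4}
  ucla_q14: {type: ordinal, lo: 1, hi: 4}

  lubben_q6:  {type: ordinal, lo: 0, hi: 5}
  lubben_q12: {type: ordinal, lo: 0, hi: 5}

  eq5d_q1: {type: ordinal, lo: 1, hi: 5}
  eq5d_q2: {type: ordinal, lo: 1, hi: 5}
  eq5d_q4: {type: ordinal, lo: 1, hi: 5}
  eq5d_q5: {type: ordinal, lo: 1, hi: 5}

  grip_kg: {type: continuous, lo: 0, hi: 90}

# Variables used by every domain model, in canonical order.  The marital
# status entry expands into one indicator column per category.
shared_features:
  - age
  - sex
  - marital_status
  - education
  - bmi
  - hearing_left
  - hearing_right
  - vision_far
  - vision_near
  - moca_total
  - phq9_total
  - sf12_q1
  - sf12_q2
  - sf12_q3
  - sf12_q4
  - sf12_q5
  - sf12_q6
  - sf12_q8
  - sf12_q10
  - sf12_q11
  - iadl_q1
  - iadl_q2
  - iadl_q3
  - iadl_q4
  - iadl_q5
  - iadl_q7
  - iadl_q8
  - ucla_q1
  - ucla_q2
  - ucla_q4
  - ucla_q11
  - ucla_q14
  - lubben_q6
  - lubben_q12
  - eq5d_q1
  - eq5d_q2
  - eq5d_q4
  - eq5d_q5

# Extra variables appended for specific domains only.
domain_extras:
  locomotion: [sppb_balance, sppb_gait, sppb_chair, sppb_gait_time, sppb_chair_time]
  sensory: []
  psychology: []
  cognition: []
  vitality: [grip_kg]
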