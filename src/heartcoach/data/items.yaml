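# Default questionnaire item bank.
#
# Behavior items use a 5-point agree scale (answer value = index + 1); an
# answer at or above the configured cutoff counts as performing the behavior.
# The scale follows the style of the European Heart Failure Self-Care
# Behaviour Scale, extended with extra behavior probes such as the
# label-reading item.  Knowledge items follow the style of the Dutch Heart
# Failure Knowledge Scale; every knowledge item carries an added
# "I don't know" option (always the last option, always scored incorrect).
#
# The full original instruments are not public in item-level detail, so this
# bank is a configurable default, not a claim of fidelity: deployments swap
# in their own bank through the same schema.

behavior_scale_options: &beh5
  - completely disagree
  - disagree
  - neither agree nor disagree
  - agree
  - completely agree

items:
  # ---- behavior items (12) -------------------------------------------
  - item_id: beh_pa_1
    behavior: physical_activity
    kind: behavior
    text: I am physically active on a regular basis
    options: *beh5
  - item_id: beh_pa_2
    behavior: physical_activity
    kind: behavior
    text: I take a walk or do comparable exercise most days
    options: *beh5
  - item_id: beh_pa_3
    behavior: physical_activity
    kind: behavior
    text: I rest in between periods of activity
    options: *beh5
  - item_id: beh_salt_1
    behavior: low_salt_diet
    kind: behavior
    text: I eat a low salt diet
    options: *beh5
  - item_id: beh_salt_2
    behavior: low_salt_diet
    kind: behavior
    text: I read the label information on food packages to know their salt (sodium) content
    options: *beh5
  - item_id: beh_salt_3
    behavior: low_salt_diet
    kind: behavior
    text: I avoid adding salt when cooking or at the table
    options: *beh5
  - item_id: beh_fluid_1
    behavior: fluid_restriction
    kind: behavior
    text: I limit the amount of fluid I drink each day
    options: *beh5
  - item_id: beh_fluid_2
    behavior: fluid_restriction
    kind: behavior
    text: I keep track of how much I drink during the day
    options: *beh5
  - item_id: beh_fluid_3
    behavior: fluid_restriction
    kind: behavior
    text: I drink less on days when my legs are more swollen
    options: *beh5
  - item_id: beh_med_1
    behavior: medication_intake
    kind: behavior
    text: I take my medication as prescribed
    options: *beh5
  - item_id: beh_med_2
    behavior: medication_intake
    kind: behavior
    text: I have a routine that helps me not to forget my medication
    options: *beh5
  - item_id: beh_med_3
    behavior: medication_intake
    kind: behavior
    text: I take my water pills also when I am away from home
    options: *beh5

  # ---- knowledge items (15) ------------------------------------------
  - item_id: know_pa_1
    behavior: physical_activity
    kind: knowledge
    text: Why is regular physical activity important in heart failure?
    options:
      - It strengthens the heart and improves fitness
      - It is only useful for losing weight
      - It should be avoided to spare the heart
      - I don't know
    correct_index: 0
  - item_id: know_pa_2
    behavior: physical_activity
    kind: knowledge
    text: What should you do if you become short of breath during exercise?
    options:
      - Push on until the session is finished
      - Slow down and rest before continuing
      - Stop exercising for the rest of the month
      - I don't know
    correct_index: 1
  - item_id: know_pa_3
    behavior: physical_activity
    kind: knowledge
    text: How often should people with heart failure be active?
    options:
      - Only when symptoms disappear
      - Once a month is sufficient
      - Regularly, on most days of the week
      - I don't know
    correct_index: 2
  - item_id: know_salt_1
    behavior: low_salt_diet
    kind: knowledge
    text: Why should people with heart failure limit salt?
    options:
      - Salt makes the body retain fluid
      - Salt raises blood sugar
      - Salt weakens the bones
      - I don't know
    correct_index: 0
  - item_id: know_salt_2
    behavior: low_salt_diet
    kind: knowledge
    text: Which food is usually high in salt?
    options:
      - Fresh fruit
      - Ready-made soups and cured meat
      - Plain rice
      - I don't know
    correct_index: 1
  - item_id: know_salt_3
    behavior: low_salt_diet
    kind: knowledge
    text: Where can you check how much salt a product contains?
    options:
      - On the price tag
      - It cannot be checked
      - On the label information of the package
      - I don't know
    correct_index: 2
  - item_id: know_fluid_1
    behavior: fluid_restriction
    kind: knowledge
    text: Why can drinking too much be harmful in heart failure?
    options:
      - Extra fluid overloads the heart and causes congestion
      - Fluid dilutes the medication
      - It causes high cholesterol
      - I don't know
    correct_index: 0
  - item_id: know_fluid_2
    behavior: fluid_restriction
    kind: knowledge
    text: What counts toward your daily fluid intake?
    options:
      - Only water
      - Only alcoholic drinks
      - All drinks, including soup, coffee, and tea
      - I don't know
    correct_index: 2
  - item_id: know_fluid_3
    behavior: fluid_restriction
    kind: knowledge
    text: A sudden weight gain of 2 kg in 3 days most likely means
    options:
      - You have gained muscle
      - Your body is retaining fluid
      - Your scales are broken
      - I don't know
    correct_index: 1
  - item_id: know_med_1
    behavior: medication_intake
    kind: knowledge
    text: Why must heart failure medication be taken every day?
    options:
      - It keeps symptoms and fluid buildup under control
      - It only works on days with symptoms
      - To avoid wasting the tablets
      - I don't know
    correct_index: 0
  - item_id: know_med_2
    behavior: medication_intake
    kind: knowledge
    text: What should you do if you feel better after some weeks?
    options:
      - Stop the medication
      - Halve every dose
      - Keep taking the medication as prescribed
      - I don't know
    correct_index: 2
  - item_id: know_med_3
    behavior: medication_intake
    kind: knowledge
    text: What do diuretics (water pills) do?
    options:
      - They thin the blood
      - They help the body get rid of excess fluid
      - They lower cholesterol
      - I don't know
    correct_index: 1
  - item_id: know_symptom_1
    behavior: symptom_monitoring
    kind: knowledge
    text: Which daily check helps detect worsening heart failure early?
    options:
      - Weighing yourself every morning
      - Measuring your height
      - Counting your steps
      - I don't know
    correct_index: 0
  - item_id: know_alcohol_1
    behavior: alcohol
    kind: knowledge
    text: What is the advice about alcohol in heart failure?
    options:
      - Alcohol is good for the heart in any amount
      - Limit alcohol; it can weaken the heart muscle
      - Only beer is safe
      - I don't know
    correct_index: 1
  - item_id: know_sleep_1
    behavior: sleep
    kind: knowledge
    text: What can help if you wake up breathless at night?
    options:
      - Sleeping with the upper body raised
      - Sleeping without a pillow
      - Drinking extra fluid before bed
      - I don't know
    correct_index: 0
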