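# Default content catalog: identifiers plus short title stubs.
#
# Media (videos, tips) are represented by identifiers only; deployments point
# these ids at real assets.  Myth/truth and barrier messages feed the
# importance/confidence feedback; feedback templates feed the weekly
# coaching feedback decision table.

items:
  # ---- education videos ------------------------------------------------
  - content_id: video_physical_activity
    behavior: physical_activity
    kind: video
    title: Being active with heart failure
  - content_id: video_low_salt_diet
    behavior: low_salt_diet
    kind: video
    title: Eating less salt day to day
  - content_id: video_fluid_restriction
    behavior: fluid_restriction
    kind: video
    title: Keeping your fluid intake in check
  - content_id: video_medication_intake
    behavior: medication_intake
    kind: video
    title: Your heart medication and why it matters
  - content_id: video_symptom_monitoring
    behavior: symptom_monitoring
    kind: video
    title: Daily weighing and symptom checks
  - content_id: video_alcohol
    behavior: alcohol
    kind: video
    title: Alcohol and the failing heart
  - content_id: video_sleep
    behavior: sleep
    kind: video
    title: Sleeping well with heart failure

  # ---- textual tips ----------------------------------------------------
  - content_id: tip_physical_activity
    behavior: physical_activity
    kind: tip
    title: Start small - a short daily walk counts
  - content_id: tip_low_salt_diet
    behavior: low_salt_diet
    kind: tip
    title: Flavor food with herbs and spices instead of salt
  - content_id: tip_fluid_restriction
    behavior: fluid_restriction
    kind: tip
    title: Spread your allowed fluid over the whole day
  - content_id: tip_medication_intake
    behavior: medication_intake
    kind: tip
    title: Link taking your pills to a fixed daily routine
  - content_id: tip_symptom_monitoring
    behavior: symptom_monitoring
    kind: tip
    title: Weigh yourself at the same time every morning
  - content_id: tip_alcohol
    behavior: alcohol
    kind: tip
    title: Agree a weekly alcohol limit with your care team
  - content_id: tip_sleep
    behavior: sleep
    kind: tip
    title: Raise the head of your bed if you wake breathless

  # ---- myth/truth messages (low perceived importance) ------------------
  - content_id: activity_not_safe
    behavior: physical_activity
    kind: myth_truth
    title: >-
      Myth: Physical activity is not safe for people with heart failure.
      Truth: It is important to be physically active and to rest regularly
      in between.
  - content_id: salt_taste_myth
    behavior: low_salt_diet
    kind: myth_truth
    title: >-
      Myth: Food without salt has no taste. Truth: Herbs and spices keep
      meals tasty while protecting your heart from fluid buildup.
  - content_id: fluid_thirst_myth
    behavior: fluid_restriction
    kind: myth_truth
    title: >-
      Myth: Drinking more is always healthier. Truth: With heart failure,
      extra fluid collects in your body and makes symptoms worse.
  - content_id: medication_feel_well_myth
    behavior: medication_intake
    kind: myth_truth
    title: >-
      Myth: When you feel well you can skip your tablets. Truth: The
      medication is what keeps you feeling well - keep taking it.

  # ---- barrier tips (low confidence) -----------------------------------
  - content_id: barrier_activity_pacing
    behavior: physical_activity
    kind: barrier_tip
    title: Short sessions with rests in between make activity manageable
  - content_id: barrier_salt_shopping
    behavior: low_salt_diet
    kind: barrier_tip
    title: Check labels while shopping - low-salt swaps are easier than cooking twice
  - content_id: barrier_fluid_measuring
    behavior: fluid_restriction
    kind: barrier_tip
    title: Use a marked bottle to see at a glance how much you have left
  - content_id: barrier_medication_reminder
    behavior: medication_intake
    kind: barrier_tip
    title: A pill organizer or phone alarm takes remembering off your mind

  # ---- readiness encouragement -----------------------------------------
  - content_id: ready_physical_activity
    behavior: physical_activity
    kind: feedback_template
    title: You rate this as important and feel confident - a great starting point
  - content_id: ready_low_salt_diet
    behavior: low_salt_diet
    kind: feedback_template
    title: You are ready to cut down on salt - let's set a first goal
  - content_id: ready_fluid_restriction
    behavior: fluid_restriction
    kind: feedback_template
    title: You are ready to manage your fluid intake - let's set a first goal
  - content_id: ready_medication_intake
    behavior: medication_intake
    kind: feedback_template
    title: You are ready to take charge of your medication - let's set a first goal

  # ---- weekly feedback templates ---------------------------------------
  - content_id: congratulate
    behavior: global
    kind: feedback_template
    title: Well done - you reached the goal you set yourself this week
  - content_id: consider_raising
    behavior: global
    kind: feedback_template
    title: You reached your goal and found it easy - consider a more ambitious goal
  - content_id: encourage_retry
    behavior: global
    kind: feedback_template
    title: You did not quite reach your goal - next week is a fresh start
  - content_id: encourage_retry_or_raise
    behavior: global
    kind: feedback_template
    title: You missed the goal but found the sessions easy - try again, perhaps with a different plan
  - content_id: reduce_goal
    behavior: global
    kind: feedback_template
    title: This week was hard - consider setting a less ambitious goal for next week
  - content_id: contact_nurse
    behavior: global
    kind: feedback_template
    title: Reaching your goals keeps being difficult - please contact your heart failure nurse
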