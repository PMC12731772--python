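# Rule base of the lifestyle recommender.
# One entry per risk class (A: low risk, B: moderate risk, C: high risk,
# D: diagnosed diabetic).  `intensity` is an ordinal (1..4) asserting that
# dietary restriction and monitoring tighten monotonically from A to D.
# Plan items carry a category (diet / activity / monitoring / referral) and
# optional structured parameters (kcal ranges, minutes per day).
classes:
  A:
    label: low-risk
    intensity: 1
    items:
      - category: activity
        text: Maintain current physical activity (25-30 min brisk walking/day).
        minutes_per_day: [25, 30]
      - category: diet
        text: Balanced meals with 50-55% complex carbohydrates, lean proteins and low saturated fat.
      - category: diet
        text: Limit sugary beverages and late-night snacking.
  B:
    label: moderate-risk
    intensity: 2
    items:
      - category: diet
        text: Maintain diet plan 2 (structured moderate-restriction menu).
      - category: diet
        text: Reduce fried food.
      - category: activity
        text: 25-30 min walking per day.
        minutes_per_day: [25, 30]
      - category: monitoring
        text: Re-assess lifestyle risk score every 6 months.
  C:
    label: high-risk
    intensity: 3
    items:
      - category: diet
        text: 1500-1700 kcal/day economical diet plan.
        kcal_per_day: [1500, 1700]
      - category: activity
        text: "Morning walking: 40 min/day."
        minutes_per_day: [40, 40]
      - category: diet
        text: Fresh vegetables from the low-cost grocery catalog.
      - category: diet
        text: Replace sugar with stevia.
      - category: activity
        text: Evening cycling or swimming recommended.
      - category: monitoring
        text: Quarterly fasting-glucose screening advised.
  D:
    label: diabetic
    intensity: 4
    items:
      - category: referral
        text: Doctor consultation.
      - category: diet
        text: Detailed diabetic diet chart with glycemic-index-based food selection.
      - category: activity
        text: Structured exercise routine supervised per clinical advice.
      - category: monitoring
        text: Regular blood-glucose monitoring and clinical follow-up.

# Exercise charts: one list for diagnosed diabetic patients, a longer one
# (adding jogging and resistance work) for the non-diabetic risk classes.
exercise_charts:
  diabetic:
    - name: walking
      text: Reduces blood sugar complications and supports weight management.
    - name: cycling
      text: Joint-friendly aerobic option when neuropathy causes joint pain.
    - name: swimming
      text: Water-based activity exercising heart, lungs and muscles with minimal joint stress.
    - name: team sports
      text: Recreational sports (basketball, soccer, softball, doubles tennis) as aerobic workouts.
    - name: yoga
      text: Helps manage blood sugar, cholesterol, weight, blood pressure, sleep and mood.
  non_diabetic:
    - name: walking
      text: Reduces blood sugar complications and supports weight management.
    - name: cycling
      text: Joint-friendly aerobic option when neuropathy causes joint pain.
    - name: swimming
      text: Water-based activity exercising heart, lungs and muscles with minimal joint stress.
    - name: team sports
      text: Recreational sports (basketball, soccer, softball, doubles tennis) as aerobic workouts.
    - name: yoga
      text: Helps manage blood sugar, cholesterol, weight, blood pressure, sleep and mood.
    - name: jogging
      text: Improves insulin sensitivity for people inclined toward diabetes.
    - name: other exercises
      text: Push-ups, squats, dumbbell rows, side planks and gym weight work.

# Static offline catalog stub standing in for live grocery price feeds.
economy_catalog:
  - item: seasonal green vegetables
    unit: kg
    price_band: low
  - item: whole-grain atta
    unit: kg
    price_band: low
  - item: pulses (mixed dal)
    unit: kg
    price_band: low
  - item: stevia sweetener
    unit: pack
    price_band: medium
  - item: unsalted nuts
    unit: 250 g
    price_band: medium
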