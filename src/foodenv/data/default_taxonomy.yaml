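# Default surveyor-taxonomy -> food-environment-class conversion rules.
#
# The Grocery, Convenience, Restaurant and Fast Food rules encode the
# published conversion (supermarket/grocery-store tags imply Grocery but a
# bare 'convenience store' tag does not; restaurant-type tags yield
# Restaurant and/or Fast Food according to the 'dine-in' / 'quick-bites'
# service flags). The source vocabulary for the remaining classes is
# proprietary and unpublished, so those tag lists are plausible inventions
# used by the synthetic generator; they are NON-CANONICAL and the file is
# meant to be extended for real directories.
meta_allowlist: [Food, Essentials, Drink]
rules:
  - rule_id: grocery-core
    any_of_tags: [supermarket, grocery store]
    disqualify_if_only: [convenience store]
    emit: [Grocery]
  - rule_id: convenience-core
    any_of_tags: [convenience store, bodega, corner store, deli grocery, newsstand]
    emit: [Convenience]
  - rule_id: restaurant-dine-in
    any_of_tags: &restaurant_type_tags
      - kosher delicatessen
      - bagel shop
      - pizzeria
      - taqueria
      - french cafe
      - diner
      - deli
      - sandwich shop
      - burger joint
      - gyro shop
      - fried chicken restaurant
      - restaurant
    required_flags: [dine-in]
    emit: [Restaurant]
  - rule_id: restaurant-quick-bites
    any_of_tags: *restaurant_type_tags
    required_flags: [quick-bites]
    emit: [FastFood]
  - rule_id: alcohol-store
    any_of_tags: [liquor store, wine shop, wine and spirits, beer distributor]
    emit: [AlcoholStore]
  - rule_id: alcohol-bar
    any_of_tags: [bar, pub, tavern, cocktail lounge, wine bar, beer hall]
    emit: [AlcoholBar]
  - rule_id: juice-coffee
    any_of_tags: [coffee shop, cafe, juice bar, tea house, smoothie shop, bubble tea]
    emit: [JuiceCoffee]
  - rule_id: sweets-desserts
    any_of_tags: [bakery, dessert shop, ice cream shop, candy store, donut shop, patisserie]
    emit: [SweetsDesserts]
  - rule_id: specialty-foods
    any_of_tags:
      - cheese shop
      - butcher
      - fish market
      - fruit market
      - health food store
      - international market
      - spice shop
    emit: [SpecialtyFoods]
  - rule_id: discount
    any_of_tags: [99 cents store, dollar store, discount store]
    emit: [Discount]
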